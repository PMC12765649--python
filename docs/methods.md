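# Methods

This note documents the models, numerical choices, and simulation conditions
behind `pupilpredict`, in the order the pipeline runs them.

## Stimulus model

Trials are 60-tone sequences at 4 Hz (200 ms tones, 250 ms onset asynchrony,
15 s per trial), with frequencies handled throughout as octaves relative to
500 Hz and quantized to a 1/12-octave grid (ties round half-to-even). Tones
are drawn from a two-source Gaussian mixture whose two centers are sampled
once per session, uniform within 500 Hz–3 kHz subject to a ≥ 1.3-octave
separation, and shared by all trials so that "distinct low-entropy" (dLE)
primary swaps refer to the same source pair. Condition parameters are
jittered per trial:

| level | σ (oct)        | p(primary)     |
|-------|----------------|----------------|
| LE    | 0.20 ± 0.15    | 0.90 ± 0.05    |
| HE    | 1.85 ± 0.15    | 0.50 ± 0.05    |

The boundary (first tone of the post segment) is uniform over tone indices
15–25; the post segment therefore has 60 − boundary tones, keeping total
trial duration fixed at 15 s. Gaussian draws falling outside 250 Hz–6 kHz
are redrawn, which keeps tones audible without reshaping the distribution
core. A default session is 9 blocks × 16 trials = 144 trials, the five
conditions allocated round-robin (29/29/29/29/28) and shuffled under one
session seed; 24-per-condition layouts are a config option.

## Dynamic regularity observer

The observer is a Bayesian change-point (run-length) filter. At tone *t* it
carries one hypothesis per candidate context length *r* ("the statistics
changed *r* tones ago"), each holding up to two Gaussian mixture components
with conjugate Normal-Inverse-Gamma (NIG) statistics. Per component the
posterior predictive is the exact Student-t of the NIG update; per
hypothesis, components are weighted by their empirical assignment counts.
The collapsed landscape weights hypotheses by their beliefs; surprisal is
the negative log mass of the observed 1/12-octave bin under that landscape,
and precision is the inverse of its total variance (law of total variance
over hypotheses and components), computed *before* the tone is observed —
the quantity that could drive anticipatory dilation. Beliefs update by
Bayes with a constant per-tone hazard; a fresh (prior) hypothesis is
injected each step with mass equal to the hazard. Run lengths are capped at
the memory parameter by folding overflow belief into the cap.

Defaults and their rationale:

* `hazard = 1/60` — one expected context change per trial; the change prior
  is not identified by anything stronger, and session statistics are flat in
  it over 1/500–1/60 (checked during development).
* `memory_m = 60` — hypotheses never span more than one trial; with
  per-trial state resets the cap never binds. We verified that running the
  filter continuously across a session (memory cap binding) changes the
  session statistics by < 0.01 and kept the simpler per-trial reset.
* `obs_noise_n = 0` octaves — observation noise is exposed but off.
* Component opening: a tone opens the second component when its weighted
  predictive bin mass under every active component falls below
  `beta × scale × (uniform bin mass over the grid)`, with `beta = 0.2` and
  `scale = 1`; the first observation of a hypothesis always seeds the first
  component.
* NIG prior: mean at the tone-band center, `kappa0 = 0.2`, `alpha0 = 1.5`,
  and scale set so the prior predictive sd equals the sd of the session's
  tones (empirical Bayes; the sd of a uniform distribution over the band is
  the standalone fallback). A weak prior is required for surprisal to track
  tone-level structure; strong priors were found to flatten the surprisal
  series and distort its correlation with precision.

The exported predictive mixture is the moment-matched Gaussian summary of
the Student-t landscape: weights, means, and variances are identical, so the
precision readout is unchanged; only deep-tail bin masses differ from the
Gaussian formula.

Known limitation: the surprisal series' lag-one autocorrelation on a default
session is ≈ 0.37, lower than the ≈ 0.48 reported for the original model on
comparable stimuli, while the surprisal–precision correlation (≈ −0.24
to −0.28) and the precision autocorrelation (≈ 0.93 vs ≈ 0.98) are close.
The three statistics trade off against each other under every faithful
variant we tried (hazard, prior strength, heavy-tailed vs Gaussian
predictives, state continuity, uniform predictive floors); the residual gap
most likely reflects an implementation detail of the released model that the
available description does not pin down.

## Fixed-window ideal observer

For each tone, a two-component Gaussian mixture is fitted to the preceding
`min(t, W)` tones (default `W = 20`); tone 0 is scored under a uniform prior
over the 56-point tone grid. Fitting is maximum-likelihood EM (5 seeded
restarts, variance floor `res²/12`, tolerance 1e-8 on the log-likelihood;
windows of < 4 points or collapsed fits fall back to one component), run
*batched*: every window of a trial — and every restart — is one row of a
masked matrix updated in lock-step, with converged rows compacted out. This
is what makes the 47-point context-window sweep (thousands of fits per
trial) run in minutes.

Scoring is Bayesian rather than plug-in: the EM responsibilities provide
soft per-component sufficient statistics, each component is scored through
its NIG Student-t posterior predictive (same priors as the change-point
observer), and weights are Dirichlet-smoothed, `(n_k + 1)/(N + 2)`. This
matters for the context-window sweep: with raw ML plug-in scoring, small
windows are overconfident and the summed log predicted probability increases
monotonically in `W` (optimum pinned at the sweep edge); with the posterior
predictive, small windows are properly regularized and the
staleness-vs-sample-size trade-off produces an interior optimum (21–24
across session seeds, consistent with the reported optimum of 20 given the
boundary position 20 ± 5).

## Pupil preprocessing

Raw gaze records (irregular ~225 Hz timestamps, pupil area in arbitrary
units, validity flags) are processed per trial:

1. time-aware linear interpolation of valid samples onto a 125 Hz grid,
   marking grid points > 2 nominal sampling steps from any valid sample;
2. 150-ms Hanning smoothing (reflection padding);
3. artifact detection on the z-scored first difference (default threshold
   3.0), segments merged when < 100 ms apart and extended 200 ms past each
   offset; detection runs on the derivative because blink edges are fast
   slope events;
4. shape-preserving PCHIP interpolation across artifact segments (edge
   segments nearest-value filled and flagged);
5. anti-aliased polyphase decimation to 40 Hz, then a zero-phase (3rd-order
   Butterworth, forward–backward) 0.1–4 Hz band-pass — zero-phase so TRF
   latencies are not shifted;
6. blink residualization: an impulse train at blink offsets convolved with
   the data-estimated mean 1.6-s post-blink waveform, removed by least
   squares.

Exclusions: trials with ≥ 35% interpolated samples or any ≥ 1.5 s
interpolated run are dropped; participants lose the lag-resolved regression
when > 50% of trials are dropped, and the condition-based analysis when any
condition falls below 13 trials.

## Temporal response functions

Each regressor contributes one value per tone, min–max normalized to [0, 1]
over the participant's session (theoretical bounds are not available in
closed form for the change-point observer; fixed bounds are a config
option). The design matrix holds time-shifted copies of the tone impulse
train for lags −0.5…4.0 s on the 40 Hz clock — 181 columns per regressor —
with surprisal and precision fitted simultaneously and trials never sharing
rows. The pupil is z-scored per trial; because that removes a per-trial
mean, design blocks are mean-centered within each trial (the exact
projection of a per-trial intercept). Omitting this demonstrably biases the
coefficients: noiseless synthetic recovery drops from exact to 0.93/0.44
correlation for the two kernels.

`ols_trf` solves by SVD least squares (minimum-norm with a warning if rank
deficient). Cross-validation targets 8 equal folds with tolerance two
(6–10), preferring the fold count closest to 8, then fewer discarded trials,
then the smaller count; surplus trials are discarded at random under a
recorded seed. Fold fits accumulate per-trial Gram and cross-product
matrices and solve the normal equations (pseudoinverse fallback), which
makes k-fold fitting k times cheaper than restacking the design; the
reported TRF is the across-fold coefficient mean, and fold quality is
held-out R² on the left-out trials.

Identifiability note: with tones exactly 10 samples apart and a
within-trial-smooth regressor (precision), lag columns 0.25 s apart are
nearly collinear; single-run precision TRFs are therefore noisy even at
moderate SNR, and precision recovery is assessed on participant-averaged
TRFs, mirroring how group TRFs are actually interpreted.

## Boundary analysis

Trial traces (optionally after regressing out the surprisal TRF prediction —
precision columns deliberately stay in) are aligned at the boundary tone's
onset, cropped to −2.5…+6 s, baseline-corrected by each trial's mean over
the baseline window, and averaged per condition. The default baseline is the
10 pre-boundary tones (2.5 s); a 0.25 s variant is configurable because the
two readings of "10 tones (250 ms)" conflict. Transition conditions are
compared with their no-transition controls (LE-dLE and LE-HE vs LE-LE;
HE-LE vs HE-HE) as per-participant difference curves restricted to 0–6 s
post-boundary.

## Group statistics

Bootstrap bands resample participants with replacement (10,000 draws, 95%
percentile interval). Cluster inference uses threshold-free cluster
enhancement (E = 0.5, H = 2, dh = max |stat|/100 — the canonical defaults)
on the per-timepoint one-sample t statistic of baseline-subtracted curves;
the permutation null (default 10,000 permutations) is the maximum absolute
enhanced value under sign flips of whole participant curves (identical to
condition-label swaps for paired contrasts), giving family-wise control
across time. Cluster p-values are `(1 + #{null ≥ cluster peak})/(n_perm+1)`,
Bonferroni-corrected across the two TRFs or three boundary contrasts.
Cohen's d reduces each participant to their mean over the cluster window,
then divides the group mean by the group sd. The implementation is
vectorized over permutations and cross-checked in the test suite against
`mne`'s TFCE permutation test.

## Synthetic pupil generator

The generator defines the conditions every downstream stage is validated
under. A participant's recording is

`pupil = Σ_g conv(tone impulses × normalized regressor_g, kernel_g)
       + boundary kernel (condition-specific) + pink noise`,

emitted at irregular (~±10% jittered) 225 Hz timestamps. Ground-truth
kernels are gamma-shaped (zero at lag 0, unimodal, < 1% of peak by 4 s):
surprisal peaking at 1.5 s with amplitude 1, precision at 0.8 s with
amplitude 0.6 (emulating the reported later-sustained vs earlier-transient
dynamics), and a boundary kernel (peak 2.2 s, amplitude 0.8) injected only
in LE-dLE trials. Pink noise has 1/f spectrum and, by default, per-trial sd
equal to the clean signal's sd (trial-level SNR ≈ 0 dB). Blinks arrive at
0.1 Hz: samples inside a 0.1–0.3 s gap are deleted, sharp partial-closure
ramps flank the gap, and a stereotyped 1.6 s recovery transient follows it.
Kernel amplitudes vary ± 20% across simulated participants.

What the generator does not emulate: luminance and gaze-angle effects,
saccade-related transients, slow vigilance drifts beyond 1/f noise,
non-linear saturation of pupil size, and any genuine brain-side surprisal
computation — the regressors *are* the generating variables. Passing
recovery tests therefore demonstrates that the pipeline estimates what it
claims to estimate under its own model class, not that real pupils obey it.

## Problem sizes in the tests

The test suite regenerates everything programmatically: full 144-trial
sessions for the session-statistics and context-window checks; a 120-trial
session with 12 simulated participants for TRF recovery; 500 null
simulations at 1,000 permutations (10 participants × 40 time points) for the
type-I calibration of the cluster test; 10 participants × 60 trials for the
boundary-detection property; and a 5-participant, 10-trial end-to-end
pipeline run. These sizes were chosen as the smallest at which each check is
statistically meaningful.
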
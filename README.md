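# pupilpredict

Model-based pupillometry of auditory predictive processing.

When people listen to a stream of tones, the pupil dilates more after tones
that are *surprising* and tracks how *precise* (reliable) the listener's
current model of the stream is. `pupilpredict` implements the full analysis
chain needed to study this with stochastic tone sequences that alternate
between low-entropy (one dominant source, narrow spread) and high-entropy
(two equiprobable, broad sources) contexts:

* **stimgen** — 60-tone trials at 4 Hz on a 1/12-octave grid, five
  conditions (LE-LE, LE-HE, LE-dLE, HE-LE, HE-HE) with a hidden
  distribution change after 20 ± 5 tones; 144-trial sessions.
* **observers** — two Bayesian observers that turn a tone sequence `x_t`
  into per-tone **surprisal** `S_{t+1} = −log P(x_{t+1} | x_{1:t})` and
  **precision** `1 / Var[Ψ_t]`, where `Ψ_t` is the predictive landscape:
  a dynamic regularity-extraction observer (run-length/change-point filter
  over Gaussian-mixture contexts) and a fixed-window ideal observer
  (windowed mixture fit, optimal window selected by likelihood sweep).
* **preprocess** — irregular eye-tracker records → clean 40 Hz pupil
  traces (resampling, Hanning smoothing, blink detection and PCHIP
  interpolation, 0.1–4 Hz zero-phase band-pass, blink regression) plus
  trial/participant exclusion rules.
* **trf** — temporal response functions by time-shifted FIR regression
  (`β̂ = (MᵀM)⁻¹Mᵀy`, lags −0.5…4 s at 40 Hz, 181 lags per regressor,
  surprisal and precision fitted jointly, 8-fold ± 2 cross-validation).
* **boundary** — boundary-locked event-related averages with surprisal
  residualization and baseline correction; transition-vs-control contrasts.
* **groupstats** — bootstrap confidence bands, threshold-free cluster
  enhancement (TFCE), sign-flip cluster permutation tests, Bonferroni
  correction, Cohen's d.
* **synthpupil** — a forward simulator (known gamma kernels, pink noise,
  blink artifacts, irregular timestamps) so the entire chain is verifiable
  by parameter recovery without any data download.
* **pipeline / CLI** — stage orchestration with seeds, manifests, and
  idempotent re-runs.

Real recordings can enter the same chain through the CSV interfaces
(`timestamp_s, pupil_area, valid` raw-gaze tables), but nothing in the
package requires them.

## Worked example

```python
import numpy as np
from pupilpredict import stimgen, observers

session = stimgen.generate_session(rng=1)       # 144 trials, seeded
traces = observers.session_traces(session, model="drex")

s = np.concatenate([t.surprisal for t in traces])
p = np.concatenate([t.precision for t in traces])
print(f"r(surprisal, precision) = {np.corrcoef(s, p)[0, 1]:.3f}")
print(f"lag-1 autocorr: surprisal {np.corrcoef(s[:-1], s[1:])[0, 1]:.3f}, "
      f"precision {np.corrcoef(p[:-1], p[1:])[0, 1]:.3f}")
```

prints

```
r(surprisal, precision) = -0.239
lag-1 autocorr: surprisal 0.368, precision 0.931
```

— the two regressors are modestly anti-correlated (unexpected tones occur
when the context model is unreliable), surprisal fluctuates tone-by-tone
while precision evolves slowly. Sweeping the ideal observer's context
window over 4–50 stimuli on the same session,

```python
best = observers.optimize_context_window(session.trials, (4, 50))
print(best)   # 21
```

recovers an optimum near 20 stimuli — the average pre-boundary context
length, past which windows increasingly straddle context changes.

A full synthetic experiment (simulate → preprocess → TRF → boundary →
group statistics) runs from one config:

```bash
pupilpredict run-all --seed 7 --out demo_out
```

after which `demo_out/groupstats/results.json` holds the significant TRF
windows and boundary-contrast clusters with corrected p-values and effect
sizes, and `demo_out/trf/trf_p*.csv` the per-participant TRF curves.

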
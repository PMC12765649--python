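"""Bayesian observer models: tone-by-tone surprisal and precision.

Two observers are implemented, matching the two ways a listener could
integrate context:

* :func:`drex_trace` — a dynamic regularity-extraction observer.  It runs a
  Bayesian change-point (run-length) filter: at every tone it entertains one
  hypothesis per possible context length ("the statistics changed r tones
  ago"), each holding a one-or-two-component Gaussian mixture with conjugate
  Normal-Inverse-Gamma sufficient statistics.  Hypothesis predictions are
  collapsed, weighted by their posterior beliefs, into a single predictive
  landscape from which surprisal (negative log bin probability of the tone
  actually heard) and precision (inverse landscape variance, computed *before*
  the tone is observed) are read out.

* :func:`ideal_observer_trace` — a fixed-window ideal observer that refits a
  two-component Gaussian mixture on the preceding ``W`` tones (default 20)
  and scores the next tone under the conjugate posterior predictive of the
  fitted components (Student-t with Dirichlet-smoothed weights, so small
  windows are regularized rather than overconfident).
  :func:`optimize_context_window` sweeps ``W`` over 4..50 and returns the
  window maximizing the summed log predicted probability.

Frequencies are in octaves re 500 Hz throughout; probabilities are masses of
1/12-octave grid bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, stdtr

from . import stimgen
from .gmm import VAR_FLOOR, fit_gmm_batch
from .mixture import (
    GRID_RES_OCT,
    PredictiveMixture,
    mixture_precision,
    surprisal_of,
)
from .stimgen import BAND_HI_OCT, BAND_LO_OCT, ToneSequence

__all__ = [
    "ObserverConfig",
    "ObserverTrace",
    "DrexState",
    "fit_window_gmm",
    "drex_step",
    "drex_trace",
    "ideal_observer_trace",
    "optimize_context_window",
    "session_traces",
    "regressor_frame",
    "regressor_statistics",
    "write_regressors",
    "read_regressors",
]

_P_FLOOR = 1e-300


@dataclass
class ObserverConfig:
    """Perceptual constraints and priors shared by both observers.

    memory_m : maximum run length (context length) in tones; the default (60,
        one trial) keeps every hypothesis within a trial.
    obs_noise_n : std (octaves) of Gaussian noise added to tones before any
        update; 0 disables it.
    beta : new-component threshold: a tone opens a second mixture component
        when its weighted predictive bin probability under every active
        component falls below ``beta * beta_scale`` times the uniform bin
        mass over the tone grid (the scaled floor that bounds the stimulus
        space).
    hazard : per-tone prior probability of a context change (default one
        expected change per 60-tone trial).
    window_W : context length of the fixed-window ideal observer.
    kappa0, alpha0, prior_mean, prior_pred_sd : Normal-Inverse-Gamma prior on
        each mixture component; defaults put a weak prior predictive at the
        center of the tone band with the sd of a uniform distribution over it.
    """

    memory_m: int = 60
    obs_noise_n: float = 0.0
    beta: float = 0.2
    beta_scale: float = 1.0
    hazard: float = 1.0 / 60.0
    max_components: int = 2
    res: float = GRID_RES_OCT
    window_W: int = 20
    grid_lo: float = BAND_LO_OCT
    grid_hi: float = BAND_HI_OCT
    prior_mean: float | None = None
    kappa0: float = 0.2
    alpha0: float = 1.5
    prior_pred_sd: float | None = None
    dirichlet_c: float = 1.0
    em_seed: int = 0

    def __post_init__(self) -> None:
        if self.memory_m < 1:
            raise ValueError("memory_m must be >= 1")
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must be a probability")
        if self.window_W < 1:
            raise ValueError("window_W must be >= 1")
        if self.prior_mean is None:
            self.prior_mean = 0.5 * (self.grid_lo + self.grid_hi)

    def resolved(self, tones: np.ndarray | None = None) -> "ObserverConfig":
        """Fill empirical-Bayes prior fields from the stimulus ensemble.

        ``prior_pred_sd = None`` means "set the prior predictive scale to the
        sd of the tones the observer will hear" (the whole session when
        available); the fallback is the sd of a uniform distribution over the
        audible band.
        """
        if self.prior_pred_sd is not None:
            return self
        if tones is not None and len(tones) > 1:
            sd = float(np.std(np.asarray(tones, dtype=float)))
        else:
            sd = (self.grid_hi - self.grid_lo) / float(np.sqrt(12.0))
        return replace(self, prior_pred_sd=sd)

    @property
    def beta0(self) -> float:
        """Inverse-Gamma scale matching the requested prior predictive sd."""
        return (
            self.prior_pred_sd**2
            * self.kappa0
            * (self.alpha0 - 1.0)
            / (self.kappa0 + 1.0)
        )

    @property
    def grid(self) -> np.ndarray:
        """1/12-octave grid points spanning the tone band."""
        k_lo = int(np.ceil(self.grid_lo / self.res - 1e-9))
        k_hi = int(np.floor(self.grid_hi / self.res + 1e-9))
        return np.arange(k_lo, k_hi + 1) * self.res


@dataclass
class ObserverTrace:
    """Per-tone surprisal (nats) and precision (1/oct^2) for one trial."""

    surprisal: np.ndarray
    precision: np.ndarray
    model: str = "drex"
    beliefs: np.ndarray | None = None  # (n_tones, memory+1) run-length posterior

    def __post_init__(self) -> None:
        self.surprisal = np.asarray(self.surprisal, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.surprisal.shape != self.precision.shape:
            raise ValueError("surprisal/precision length mismatch")
        if np.any(self.surprisal < -1e-12):
            raise ValueError("negative surprisal")
        if np.any(self.precision <= 0):
            raise ValueError("non-positive precision")

    def __len__(self) -> int:
        return len(self.surprisal)


# --------------------------------------------------------------------------
# windowed maximum-likelihood mixture fit (ideal observer building block)
# --------------------------------------------------------------------------

def fit_window_gmm(
    window: Sequence[float],
    n_components: int = 2,
    var_floor: float = VAR_FLOOR,
    seed: int = 0,
) -> PredictiveMixture:
    """ML two-component Gaussian mixture fit of a context window.

    EM with 5 seeded restarts, variance floor, tolerance 1e-8; windows with
    fewer than 4 points (or collapsed fits) fall back to a single component
    with the second weight exactly 0.
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    if n_components not in (1, 2):
        raise ValueError("only 1 or 2 components supported")
    if n_components == 1:
        mu = float(w.mean())
        var = max(float(w.var()), var_floor)
        return PredictiveMixture([1.0], [mu], [np.sqrt(var)])
    fit = fit_gmm_batch(w[None, :], var_floor=var_floor, seed=seed)
    order = np.argsort(-fit["weights"][0])  # dominant component first
    return PredictiveMixture(
        fit["weights"][0][order],
        fit["means"][0][order],
        np.sqrt(fit["vars"][0][order]),
    )


# --------------------------------------------------------------------------
# D-REX-style run-length observer
# --------------------------------------------------------------------------

@dataclass
class DrexState:
    """Run-length hypotheses: row ``r`` = "context began ``r`` tones ago".

    Per hypothesis, up to two mixture components carry conjugate sufficient
    statistics (count, mean, centered sum of squares); component weights are
    the empirical assignment proportions.
    """

    belief: np.ndarray       # (H,)
    comp_n: np.ndarray       # (H, 2)
    comp_mean: np.ndarray    # (H, 2)
    comp_m2: np.ndarray      # (H, 2)

    @classmethod
    def initial(cls) -> "DrexState":
        return cls(
            belief=np.ones(1),
            comp_n=np.zeros((1, 2)),
            comp_mean=np.zeros((1, 2)),
            comp_m2=np.zeros((1, 2)),
        )

    @property
    def n_hypotheses(self) -> int:
        return len(self.belief)


def _posterior_predictive(cfg: ObserverConfig, n, mean, m2):
    """Student-t posterior predictive of a NIG component.

    Returns ``(mun, nu, scale, var)``: the conjugate Normal-Inverse-Gamma
    update gives a Student-t predictive with ``nu = 2 * alpha_n`` degrees of
    freedom; ``var`` is its variance (plus observation-noise variance), used
    for the moment-matched landscape and the precision readout.
    """
    k0, a0, b0, mu0 = cfg.kappa0, cfg.alpha0, cfg.beta0, cfg.prior_mean
    kn = k0 + n
    mun = (k0 * mu0 + n * mean) / kn
    an = a0 + n / 2.0
    bn = b0 + m2 / 2.0 + k0 * n * (mean - mu0) ** 2 / (2.0 * kn)
    nu = 2.0 * an
    scale2 = bn * (kn + 1.0) / (an * kn)
    var = scale2 * nu / (nu - 2.0) + cfg.obs_noise_n**2
    return mun, nu, np.sqrt(scale2), var


def _bin_prob(x, mu, var, res):
    """Gaussian bin mass (used by the ideal observer's fitted mixtures)."""
    sd = np.sqrt(var)
    return ndtr((x + res / 2.0 - mu) / sd) - ndtr((x - res / 2.0 - mu) / sd)


def _t_bin_prob(x, mu, nu, scale, res):
    """Student-t bin mass (exact conjugate predictive of the NIG model)."""
    return stdtr(nu, (x + res / 2.0 - mu) / scale) - stdtr(
        nu, (x - res / 2.0 - mu) / scale
    )


def _hypothesis_mixture(state: DrexState, cfg: ObserverConfig):
    """Per-hypothesis predictive parameters, all shaped (H, 2)."""
    mun, nu, scale, var = _posterior_predictive(
        cfg, state.comp_n, state.comp_mean, state.comp_m2
    )
    total = state.comp_n.sum(axis=1, keepdims=True)
    w = np.where(total > 0, state.comp_n / np.maximum(total, 1.0), 0.0)
    # fresh hypotheses (no data): all mass on the prior-predictive component
    w[total[:, 0] == 0, 0] = 1.0
    return w, mun, nu, scale, var


def drex_step(
    state: DrexState, x: float, cfg: ObserverConfig
) -> tuple[DrexState, PredictiveMixture, float, float]:
    """Score one tone under the current state, then update the state.

    Returns ``(new_state, predictive, surprisal, precision)`` where the
    predictive mixture and precision describe the landscape *before* the tone
    was observed.  Surprisal uses the exact Student-t predictive bin mass;
    the returned :class:`PredictiveMixture` is its moment-matched Gaussian
    summary (identical means, weights and variances).
    """
    if not np.isfinite(x):
        raise ValueError("non-finite tone value")
    cfg = cfg.resolved()
    w, mun, nu, scale, var = _hypothesis_mixture(state, cfg)
    flat_w = (state.belief[:, None] * w).ravel()
    keep = flat_w > 0
    mix = PredictiveMixture(
        flat_w[keep] / flat_w[keep].sum(),
        mun.ravel()[keep],
        np.sqrt(var.ravel()[keep]),
    )
    precision = mixture_precision(mix)

    # per-component / per-hypothesis bin mass of the observed tone
    p_comp = _t_bin_prob(x, mun, nu, scale, cfg.res)  # (H, 2)
    p_tone = float(np.sum((state.belief[:, None] * w) * p_comp))
    surprisal = float(surprisal_of(np.clip(p_tone, _P_FLOOR, 1.0)))
    lik = np.maximum((w * p_comp).sum(axis=1), _P_FLOOR)

    # belief update: grow runs, inject a change-point hypothesis
    grown = state.belief * lik * (1.0 - cfg.hazard)
    b_cp = float(np.sum(state.belief * lik) * cfg.hazard)
    belief = np.concatenate([[b_cp], grown])
    belief /= belief.sum()

    # sufficient-statistics update (each hypothesis absorbs x, run length +1)
    n = state.comp_n.copy()
    mean = state.comp_mean.copy()
    m2 = state.comp_m2.copy()
    n_active = (n > 0).sum(axis=1)
    total = n.sum(axis=1)

    # choose target component per hypothesis: a tone opens the second
    # component when its scaled responsibility under every active component
    # falls below beta times the uniform bin mass over the tone grid
    resp = w * p_comp
    assign = resp.argmax(axis=1)
    assign[total == 0] = 0  # first observation goes to the prior component
    if cfg.max_components > 1:
        uniform_mass = cfg.res / (cfg.grid_hi - cfg.grid_lo)
        open_new = (
            (n_active == 1)
            & (n_active < cfg.max_components)
            & (resp.max(axis=1) < cfg.beta * cfg.beta_scale * uniform_mass)
        )
        assign[open_new] = 1

    rows = np.arange(len(assign))
    n_sel = n[rows, assign]
    delta = x - mean[rows, assign]
    n_new = n_sel + 1.0
    mean_new = mean[rows, assign] + delta / n_new
    m2_new = m2[rows, assign] + delta * (x - mean_new)
    n[rows, assign] = n_new
    mean[rows, assign] = mean_new
    m2[rows, assign] = m2_new

    empty = np.zeros((1, 2))
    new_state = DrexState(
        belief=belief,
        comp_n=np.concatenate([empty, n]),
        comp_mean=np.concatenate([empty, mean]),
        comp_m2=np.concatenate([empty, m2]),
    )

    # memory truncation: fold run lengths beyond m into the r = m hypothesis
    if new_state.n_hypotheses > cfg.memory_m + 1:
        m_idx = cfg.memory_m
        overflow = new_state.belief[m_idx + 1 :].sum()
        new_state.belief = new_state.belief[: m_idx + 1].copy()
        new_state.belief[m_idx] += overflow
        new_state.comp_n = new_state.comp_n[: m_idx + 1]
        new_state.comp_mean = new_state.comp_mean[: m_idx + 1]
        new_state.comp_m2 = new_state.comp_m2[: m_idx + 1]

    return new_state, mix, surprisal, precision


def drex_trace(
    seq: ToneSequence | Sequence[float],
    cfg: ObserverConfig | None = None,
    keep_beliefs: bool = False,
    rng: np.random.Generator | None = None,
) -> ObserverTrace:
    """Run the run-length observer over one trial (state reset at tone 0)."""
    cfg = (cfg or ObserverConfig()).resolved()
    x = seq.freqs if isinstance(seq, ToneSequence) else np.asarray(seq, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sequence")
    if cfg.obs_noise_n > 0:
        if rng is None:
            raise ValueError("obs_noise_n > 0 requires an rng")
        x = x + rng.normal(0.0, cfg.obs_noise_n, size=len(x))

    state = DrexState.initial()
    S = np.empty(len(x))
    P = np.empty(len(x))
    beliefs = np.zeros((len(x), cfg.memory_m + 1)) if keep_beliefs else None
    for t, xt in enumerate(x):
        if keep_beliefs:
            b = state.belief
            beliefs[t, : len(b)] = b
        state, _, S[t], P[t] = drex_step(state, float(xt), cfg)
    return ObserverTrace(S, P, model="drex", beliefs=beliefs)


# --------------------------------------------------------------------------
# fixed-window ideal observer
# --------------------------------------------------------------------------

def _uniform_grid_scores(cfg: ObserverConfig) -> tuple[float, float]:
    """Surprisal and precision of a uniform prior over the tone grid."""
    grid = cfg.grid
    s0 = float(np.log(len(grid)))
    p0 = 1.0 / float(np.var(grid))
    return s0, p0


def _windows_matrix(x: np.ndarray, ts: np.ndarray, widths: np.ndarray):
    """Stack windows ``x[t-w:t]`` into a NaN-padded (len(ts), max_w) matrix."""
    max_w = int(widths.max())
    out = np.full((len(ts), max_w), np.nan)
    for i, (t, w) in enumerate(zip(ts, widths)):
        out[i, :w] = x[t - w : t]
    return out, ~np.isnan(out)


def _batch_scores(
    x_next: np.ndarray, fit: dict[str, np.ndarray], cfg: ObserverConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Surprisal and precision of each row's next tone, posterior predictive.

    The EM point fit supplies soft per-component sufficient statistics; each
    component's predictive is then the Student-t of the conjugate
    Normal-Inverse-Gamma update of those statistics, and component weights are
    Dirichlet-smoothed (``(n_k + c) / (N + K c)``), so a rarely-seen second
    category keeps a small probability floor.
    """
    nk, xbar, ss = fit["counts"], fit["xbar"], fit["ss"]
    mun, nu, scale, var = _posterior_predictive(cfg, nk, xbar, ss)
    c = cfg.dirichlet_c
    w = (nk + c) / (nk.sum(axis=1, keepdims=True) + 2.0 * c)
    p = (w * _t_bin_prob(x_next[:, None], mun, nu, scale, cfg.res)).sum(axis=1)
    p = np.clip(p, _P_FLOOR, 1.0)
    m = (w * mun).sum(axis=1)
    tot_var = (w * (var + mun**2)).sum(axis=1) - m**2
    return -np.log(p), 1.0 / np.maximum(tot_var, 1e-12)


def ideal_observer_trace(
    seq: ToneSequence | Sequence[float], cfg: ObserverConfig | None = None
) -> ObserverTrace:
    """Score a trial with the fixed-window observer (window ``cfg.window_W``).

    Tone 0 is scored under a uniform prior over the grid; tone t under a
    two-component mixture refit on the preceding ``min(t, W)`` tones and
    scored through its conjugate posterior predictive.
    """
    cfg = (cfg or ObserverConfig()).resolved()
    x = seq.freqs if isinstance(seq, ToneSequence) else np.asarray(seq, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sequence")
    S = np.empty(len(x))
    P = np.empty(len(x))
    S[0], P[0] = _uniform_grid_scores(cfg)
    if len(x) > 1:
        ts = np.arange(1, len(x))
        widths = np.minimum(ts, cfg.window_W)
        wins, mask = _windows_matrix(x, ts, widths)
        fit = fit_gmm_batch(wins, mask, seed=cfg.em_seed)
        S[1:], P[1:] = _batch_scores(x[1:], fit, cfg)
    return ObserverTrace(S, P, model="ideal")


def optimize_context_window(
    sequences: Iterable[ToneSequence | Sequence[float]],
    w_range: tuple[int, int] = (4, 50),
    cfg: ObserverConfig | None = None,
    return_loglik: bool = False,
):
    """Window size in ``w_range`` maximizing summed log predicted probability.

    For every trial, each unique (tone, effective-window) pair is fitted once
    in a single batched EM call; the per-window totals are then assembled from
    the shared table.  Ties break toward the smaller window.
    """
    w_lo, w_hi = int(w_range[0]), int(w_range[1])
    if w_hi < w_lo:
        raise ValueError("empty window range")
    seqs = [
        s.freqs if isinstance(s, ToneSequence) else np.asarray(s, dtype=float)
        for s in sequences
    ]
    if not seqs:
        raise ValueError("at least one sequence required")
    cfg = (cfg or ObserverConfig()).resolved(np.concatenate(seqs))

    Ws = np.arange(w_lo, w_hi + 1)
    total = np.zeros(len(Ws))
    s0 = -float(np.log(len(cfg.grid)))
    for x in seqs:
        n = len(x)
        pairs = sorted(
            {(t, min(t, W)) for t in range(1, n) for W in Ws}
        )
        ts = np.array([p[0] for p in pairs])
        widths = np.array([p[1] for p in pairs])
        wins, mask = _windows_matrix(x, ts, widths)
        fit = fit_gmm_batch(wins, mask, seed=cfg.em_seed)
        neg_s, _ = _batch_scores(x[ts], fit, cfg)
        table = {pair: -neg_s[i] for i, pair in enumerate(pairs)}
        for j, W in enumerate(Ws):
            total[j] += s0 + sum(
                table[(t, min(t, int(W)))] for t in range(1, n)
            )
    best = int(Ws[np.argmax(total)])  # argmax returns first (smallest W) tie
    return (best, dict(zip(Ws.tolist(), total.tolist()))) if return_loglik else best


# --------------------------------------------------------------------------
# session-level helpers and I/O
# --------------------------------------------------------------------------

def session_traces(
    session: stimgen.Session,
    cfg: ObserverConfig | None = None,
    model: str = "drex",
    rng: np.random.Generator | None = None,
) -> list[ObserverTrace]:
    """Observer traces for every trial of a session (state reset per trial).

    With ``cfg.prior_pred_sd`` unset, the observer's prior predictive scale is
    resolved empirically from the whole session's tones (empirical Bayes).
    """
    cfg = cfg or ObserverConfig()
    cfg = cfg.resolved(np.concatenate([t.freqs for t in session.trials]))
    if model == "drex":
        return [drex_trace(t, cfg, rng=rng) for t in session.trials]
    if model == "ideal":
        return [ideal_observer_trace(t, cfg) for t in session.trials]
    raise ValueError(f"unknown model {model!r}")


def regressor_frame(
    session: stimgen.Session, traces: Sequence[ObserverTrace], model: str
) -> pd.DataFrame:
    rows = []
    for i, (trial, tr) in enumerate(zip(session.trials, traces)):
        rows.append(
            pd.DataFrame(
                {
                    "trial": i,
                    "tone_index": np.arange(len(trial)),
                    "onset_s": trial.onsets,
                    "surprisal": tr.surprisal,
                    "precision": tr.precision,
                    "model": model,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _lag1(series: np.ndarray) -> float:
    if len(series) < 3 or np.std(series[:-1]) == 0 or np.std(series[1:]) == 0:
        return np.nan
    return float(np.corrcoef(series[:-1], series[1:])[0, 1])


def regressor_statistics(traces: Sequence[ObserverTrace]) -> dict[str, float]:
    """Session-level regressor statistics.

    ``surprisal_precision_r``: Pearson r between the two regressors over all
    tones concatenated across trials.  ``surprisal_lag1`` / ``precision_lag1``:
    lag-one autocorrelation computed within each trial and averaged.
    """
    s_all = np.concatenate([t.surprisal for t in traces])
    p_all = np.concatenate([t.precision for t in traces])
    r = float(np.corrcoef(s_all, p_all)[0, 1])
    s_ac = np.nanmean([_lag1(t.surprisal) for t in traces])
    p_ac = np.nanmean([_lag1(t.precision) for t in traces])
    return {
        "surprisal_precision_r": r,
        "surprisal_lag1": float(s_ac),
        "precision_lag1": float(p_ac),
    }


def write_regressors(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_regressors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
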
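"""Temporal response functions by time-shifted FIR least squares (rERP).

Each regressor (surprisal, precision) contributes one continuous value per
tone.  The design matrix holds time-shifted copies of the tone impulse train
at every lag from -0.5 s to 4.0 s on the 40 Hz clock (181 columns per
regressor); plain OLS then yields lag-resolved coefficients that read as an
impulse response of the pupil to a unit change of the regressor.  Trials
never share rows, the pupil is z-scored per trial, and regressors are min-max
normalized to [0, 1].  Cross-validation targets 8 folds with a tolerance of
two (6..10), discarding surplus trials to equalize fold sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LAG_MIN_S",
    "LAG_MAX_S",
    "FS",
    "EventSeries",
    "TRFEstimate",
    "zscore_trial",
    "normalize_regressor",
    "lag_grid",
    "build_design_matrix",
    "ols_trf",
    "crossval_trf",
    "choose_folds",
    "predict_from_trf",
]

FS = 40.0
LAG_MIN_S = -0.5
LAG_MAX_S = 4.0


def lag_grid(fs: float = FS) -> np.ndarray:
    """Lag times in seconds; 181 lags at 40 Hz."""
    return np.arange(int(round(LAG_MIN_S * fs)), int(round(LAG_MAX_S * fs)) + 1) / fs


N_LAGS = len(lag_grid())


@dataclass
class EventSeries:
    """One trial's tone events: onset sample indices plus regressor values."""

    onsets: np.ndarray                  # sample indices on the 40 Hz clock
    values: dict[str, np.ndarray]       # regressor name -> value per tone
    n_samples: int                      # trial length in samples

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for name, v in self.values.items():
            if len(v) != len(self.onsets):
                raise ValueError(f"regressor {name!r} length mismatch")
            if np.any((v < -1e-9) | (v > 1 + 1e-9)):
                raise ValueError(f"regressor {name!r} not normalized to [0, 1]")
        if np.any((self.onsets < 0) | (self.onsets >= self.n_samples)):
            raise ValueError("tone onset outside trial extent")


@dataclass
class TRFEstimate:
    """Lag-resolved coefficients per regressor."""

    lags: np.ndarray
    coefficients: dict[str, np.ndarray]
    fold_id: int | None = None
    heldout_r2: float | None = None

    def __post_init__(self) -> None:
        for name, c in self.coefficients.items():
            if len(c) != len(self.lags):
                raise ValueError(f"coefficient curve {name!r} length mismatch")


def zscore_trial(y: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-population-sd per trial; constant trials -> zeros."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty trial")
    if y.size < 2:
        raise ValueError("trial too short to z-score")
    sd = y.std()
    if sd == 0:
        warnings.warn("constant trial z-scored to zeros")
        return np.zeros_like(y)
    return (y - y.mean()) / sd


def normalize_regressor(
    values: np.ndarray, v_min: float, v_max: float
) -> np.ndarray:
    """Affine map of regressor values onto [0, 1], clipped."""
    if not v_max > v_min:
        raise ValueError("v_max must exceed v_min")
    return np.clip((np.asarray(values, dtype=float) - v_min) / (v_max - v_min), 0.0, 1.0)


def build_design_matrix(
    events: Sequence[EventSeries], fs: float = FS, center: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Stack per-trial time-expanded design blocks.

    Column (g, l) holds the value of a tone of regressor g whose onset lies
    ``lags[l]`` seconds before the row's sample, zero elsewhere; rows of
    different trials never mix.  With ``center`` (default), columns are
    mean-centered within each trial block, which absorbs the per-trial
    intercept implied by per-trial z-scoring of the target; without it the
    trial-mean removal would bias the coefficients.  Returns the dense matrix
    and the column regressor names (each name spans ``N_LAGS`` consecutive
    columns, lag-ordered).
    """
    if not events:
        raise ValueError("no trials")
    names = list(events[0].values)
    lag_samples = np.round(lag_grid(fs) * fs).astype(int)
    blocks = []
    for ev in events:
        m = np.zeros((ev.n_samples, len(names) * N_LAGS))
        for g, name in enumerate(names):
            vals = ev.values[name]
            for onset, v in zip(ev.onsets, vals):
                rows = onset + lag_samples
                ok = (rows >= 0) & (rows < ev.n_samples)
                m[rows[ok], g * N_LAGS + np.flatnonzero(ok)] += v
        if center:
            m -= m.mean(axis=0, keepdims=True)
        blocks.append(m)
    return np.vstack(blocks), names


def ols_trf(M: np.ndarray, y: np.ndarray, names: Sequence[str]) -> TRFEstimate:
    """Least-squares TRF via SVD (``lstsq``); minimum-norm if rank-deficient."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    if M.shape[0] != len(y):
        raise ValueError("design/target dimension mismatch")
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    coeffs = {
        name: beta[g * N_LAGS : (g + 1) * N_LAGS] for g, name in enumerate(names)
    }
    return TRFEstimate(lag_grid(), coeffs)


def predict_from_trf(
    events: Sequence[EventSeries],
    trf: TRFEstimate,
    regressors: Sequence[str] | None = None,
    fs: float = FS,
    center: bool = True,
) -> list[np.ndarray]:
    """Per-trial model prediction from selected regressors of a TRF.

    With ``center`` the prediction is mean-centered per trial, matching a
    design whose blocks were trial-centered and a per-trial z-scored target.
    """
    regressors = list(trf.coefficients) if regressors is None else list(regressors)
    lag_samples = np.round(trf.lags * fs).astype(int)
    out = []
    for ev in events:
        yhat = np.zeros(ev.n_samples)
        for name in regressors:
            beta = trf.coefficients[name]
            for onset, v in zip(ev.onsets, ev.values[name]):
                rows = onset + lag_samples
                ok = (rows >= 0) & (rows < ev.n_samples)
                yhat[rows[ok]] += v * beta[ok]
        if center:
            yhat -= yhat.mean()
        out.append(yhat)
    return out


def choose_folds(
    n_trials: int, target: int = 8, tolerance: int = 2
) -> tuple[int, int]:
    """Fold count k in [target-tolerance, target+tolerance] and trials
    discarded, preferring k closest to the target, then fewer discards, then
    smaller k."""
    lo, hi = target - tolerance, target + tolerance
    if n_trials < lo:
        raise ValueError(f"need at least {lo} trials for cross-validation")
    options = []
    for k in range(lo, hi + 1):
        per = n_trials // k
        if per == 0:
            continue
        discard = n_trials - k * per
        options.append((abs(k - target), discard, k))
    if not options:
        raise ValueError("no feasible fold configuration")
    _, discard, k = min(options)
    return k, discard


def _gram_blocks(events, y_trials):
    """Per-trial Gram (M'M) and cross-product (M'y) accumulation."""
    grams, cross, sizes, ss = [], [], [], []
    names = list(events[0].values)
    for ev, y in zip(events, y_trials):
        M, _ = build_design_matrix([ev])
        grams.append(M.T @ M)
        cross.append(M.T @ y)
        sizes.append(len(y))
        ss.append(float(y @ y))
    return names, grams, cross, sizes, ss


def crossval_trf(
    events: Sequence[EventSeries],
    y_trials: Sequence[np.ndarray],
    rng: np.random.Generator | int | None = None,
    target_folds: int = 8,
    tolerance: int = 2,
) -> tuple[list[TRFEstimate], TRFEstimate, dict]:
    """K-fold cross-validated TRF (k in [6, 10], surplus trials discarded).

    Per fold, the TRF is fitted on the training trials (normal equations
    accumulated per trial, solved by a pseudoinverse-backed solver) and
    scored as held-out R^2 on the left-out fold.  Returns per-fold
    estimates, their coefficient average, and a report.
    """
    if len(events) != len(y_trials):
        raise ValueError("events/targets length mismatch")
    k, discard = choose_folds(len(events), target_folds, tolerance)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    order = rng.permutation(len(events))
    used = order[: len(events) - discard]
    folds = np.array_split(used, k)

    names, grams, cross, sizes, ss = _gram_blocks(list(events), list(y_trials))
    G_tot = np.sum(grams, axis=0)
    c_tot = np.sum(cross, axis=0)

    estimates = []
    for fold_id, fold in enumerate(folds):
        G = G_tot - np.sum([grams[i] for i in fold], axis=0)
        c = c_tot - np.sum([cross[i] for i in fold], axis=0)
        try:
            beta = np.linalg.solve(G, c)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(G, c, rcond=None)[0]
        # held-out R^2 over the concatenated left-out trials
        sse = 0.0
        sst = 0.0
        for i in fold:
            yhat = predict_from_trf(
                [events[i]],
                TRFEstimate(
                    lag_grid(),
                    {
                        n: beta[g * N_LAGS : (g + 1) * N_LAGS]
                        for g, n in enumerate(names)
                    },
                ),
            )[0]
            resid = y_trials[i] - yhat
            sse += float(resid @ resid)
            sst += float(y_trials[i] @ y_trials[i])
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        estimates.append(
            TRFEstimate(
                lag_grid(),
                {n: beta[g * N_LAGS : (g + 1) * N_LAGS] for g, n in enumerate(names)},
                fold_id=fold_id,
                heldout_r2=r2,
            )
        )

    mean_trf = TRFEstimate(
        lag_grid(),
        {
            n: np.mean([e.coefficients[n] for e in estimates], axis=0)
            for n in names
        },
    )
    report = {
        "n_trials": len(events),
        "k_folds": k,
        "n_discarded": discard,
        "heldout_r2": [e.heldout_r2 for e in estimates],
    }
    return estimates, mean_trf, report
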
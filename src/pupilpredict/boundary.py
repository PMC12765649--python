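"""Boundary-locked event-related pupil analysis.

Within each trial the generating tone distribution may change at the boundary
tone; this module aligns pupil traces at that tone's onset, baseline-corrects
each trial, and averages per condition.  To isolate context-shift responses
from tone-level unexpectedness, the variance explained by the surprisal TRF
can first be regressed out of the trace (the precision contribution is
deliberately left in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trf import EventSeries, TRFEstimate, predict_from_trf

__all__ = [
    "BoundaryERP",
    "residualize_surprisal",
    "boundary_erp",
    "condition_contrast",
    "DEFAULT_WINDOW_S",
    "DEFAULT_BASELINE_S",
]

DEFAULT_WINDOW_S = (-2.5, 6.0)
#: ten tones before the boundary (2.5 s at 4 Hz); configurable
DEFAULT_BASELINE_S = (-2.5, 0.0)


@dataclass
class BoundaryERP:
    """Boundary-locked average for one condition."""

    condition: str
    times: np.ndarray            # seconds relative to boundary onset
    mean: np.ndarray
    per_trial: np.ndarray        # (n_trials, n_times), baseline-corrected

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.per_trial = np.atleast_2d(np.asarray(self.per_trial, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.per_trial.shape[0]

    def to_frame(self, participant: str | int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": participant,
                "condition": self.condition,
                "t_rel_boundary": self.times,
                "value": self.mean,
            }
        )


def residualize_surprisal(
    y_trials: Sequence[np.ndarray],
    events: Sequence[EventSeries],
    trf_fit: TRFEstimate,
    regressor: str = "surprisal",
) -> list[np.ndarray]:
    """Subtract the surprisal-TRF prediction from each trial's trace.

    Only the named regressor's columns are removed; other regressors
    (precision) stay in the signal.
    """
    if trf_fit is None or regressor not in trf_fit.coefficients:
        raise ValueError(f"no fitted TRF for regressor {regressor!r}")
    preds = predict_from_trf(list(events), trf_fit, [regressor])
    return [y - yhat for y, yhat in zip(y_trials, preds)]


def boundary_erp(
    trials: Sequence[tuple[np.ndarray, int]],
    condition: str,
    fs: float = 40.0,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    baseline_s: tuple[float, float] = DEFAULT_BASELINE_S,
) -> BoundaryERP:
    """Boundary-locked, baseline-corrected event-related average.

    ``trials`` holds ``(trace_samples, boundary_sample_index)`` pairs; each
    trial is cropped to ``window_s`` around the boundary onset, its
    ``baseline_s`` mean subtracted, then trials are averaged.
    """
    if not trials:
        raise ValueError(f"no trials for condition {condition!r}")
    i_lo = int(round(window_s[0] * fs))
    i_hi = int(round(window_s[1] * fs))
    times = np.arange(i_lo, i_hi + 1) / fs
    b_lo = int(round(baseline_s[0] * fs))
    b_hi = int(round(baseline_s[1] * fs))

    rows = []
    for y, b_idx in trials:
        lo, hi = b_idx + i_lo, b_idx + i_hi
        if lo < 0 or hi >= len(y):
            raise ValueError("boundary window exceeds trial extent")
        seg = np.asarray(y[lo : hi + 1], dtype=float)
        base = np.asarray(y[b_idx + b_lo : b_idx + b_hi + 1], dtype=float)
        rows.append(seg - base.mean())
    per_trial = np.vstack(rows)
    return BoundaryERP(condition, times, per_trial.mean(axis=0), per_trial)


def condition_contrast(
    erp_a: BoundaryERP,
    erp_control: BoundaryERP,
    window_s: tuple[float, float] = (0.0, 6.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Transition-minus-control difference curve, cropped post-boundary.

    Returns ``(times, difference)`` restricted to ``window_s`` after the
    boundary.  Both inputs must share a time axis.
    """
    if erp_a.times.shape != erp_control.times.shape or np.any(
        np.abs(erp_a.times - erp_control.times) > 1e-9
    ):
        raise ValueError("time axes differ between conditions")
    sel = (erp_a.times >= window_s[0] - 1e-9) & (erp_a.times <= window_s[1] + 1e-9)
    return erp_a.times[sel], (erp_a.mean - erp_control.mean)[sel]


def erp_frame(
    erps: Sequence[BoundaryERP], participant: str | int = 0
) -> pd.DataFrame:
    """Long-format table of boundary ERPs (one row per condition x time)."""
    return pd.concat([e.to_frame(participant) for e in erps], ignore_index=True)
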
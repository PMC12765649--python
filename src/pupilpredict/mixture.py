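"""Gaussian-mixture predictive landscapes: probability, surprisal, precision.

Both observer models summarize their expectation about the next tone as a
mixture of Gaussians over octave space (the predictive landscape).  Because
tones live on a discrete 1/12-octave grid, the probability of a tone is the
mixture mass inside its grid bin, and surprisal is the negative log of that
mass.  Precision is the inverse variance of the (continuous) landscape,
computed by the law of total variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

logger = logging.getLogger(__name__)

GRID_RES_OCT = 1.0 / 12.0
_VAR_EPS = 1e-12
_P_FLOOR = 1e-300


@dataclass
class PredictiveMixture:
    """Collapsed predictive distribution over the next tone (octaves)."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.stds = np.atleast_1d(np.asarray(self.stds, dtype=float))
        if not (self.weights.shape == self.means.shape == self.stds.shape):
            raise ValueError("weights/means/stds shape mismatch")
        if np.any(self.stds <= 0):
            raise ValueError("mixture stds must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def mixture_tone_probability(
    mix: PredictiveMixture, x: float | np.ndarray, res: float = GRID_RES_OCT
) -> float | np.ndarray:
    """Probability mass of the grid bin centered at ``x`` (width ``res``)."""
    x_arr = np.asarray(x, dtype=float)[..., None]
    z_hi = (x_arr + res / 2.0 - mix.means) / mix.stds
    z_lo = (x_arr - res / 2.0 - mix.means) / mix.stds
    p = np.sum(mix.weights * (ndtr(z_hi) - ndtr(z_lo)), axis=-1)
    p = np.clip(p, _P_FLOOR, 1.0)
    return float(p) if np.isscalar(x) else p


def mixture_mean_variance(mix: PredictiveMixture) -> tuple[float, float]:
    """Mean and total variance of the mixture (law of total variance)."""
    m = float(np.sum(mix.weights * mix.means))
    second = float(np.sum(mix.weights * (mix.stds**2 + mix.means**2)))
    return m, second - m**2


def mixture_precision(mix: PredictiveMixture) -> float:
    """Inverse of the landscape's total variance, 1/oct^2."""
    _, var = mixture_mean_variance(mix)
    if var < _VAR_EPS:
        logger.warning("mixture variance below floor; precision capped")
        var = _VAR_EPS
    return 1.0 / var


def surprisal_of(p: float | np.ndarray) -> float | np.ndarray:
    """Negative log probability in nats; zero iff the event was certain."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr > 1.0):
        raise ValueError("probability must lie in (0, 1]")
    out = -np.log(p_arr)
    return float(out) if np.isscalar(p) else out
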
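"""Group-level inference for time-resolved pupil curves.

Implements the statistics used on TRF and boundary-ERP curves: participant
bootstrap confidence bands, threshold-free cluster enhancement (TFCE),
cluster-based permutation tests (sign-flip for one-sample designs, which is
equivalent to condition-label swaps for paired contrasts), Bonferroni
correction, and Cohen's d effect sizes over cluster windows.

TFCE integrates ``extent^E * height^H`` over thresholds up to each point's
statistic, removing the arbitrary cluster-forming threshold; the permutation
null is the maximum enhanced value per permutation, giving family-wise
control over time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterResult",
    "bootstrap_ci",
    "tfce",
    "cluster_permutation",
    "bonferroni",
    "cohens_d",
]

TFCE_E = 0.5
TFCE_H = 2.0


@dataclass
class Cluster:
    t_start: float
    t_end: float
    tfce_mass: float
    p_corrected: float
    effect_size_d: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    enhanced: np.ndarray
    threshold: float           # (1 - alpha) quantile of the max-null
    n_permutations: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def bootstrap_ci(
    curves: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap band for the participant-mean curve.

    Participants (rows) are resampled with replacement ``n_boot`` times; the
    pointwise ``(1-level)/2`` and ``(1+level)/2`` percentiles of the resampled
    means form the band.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n = curves.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = curves[idx].mean(axis=1)
    lo = np.percentile(means, 100 * (1 - level) / 2, axis=0)
    hi = np.percentile(means, 100 * (1 + level) / 2, axis=0)
    return lo, hi


def _runs_extent(above: np.ndarray) -> np.ndarray:
    """Per-element length of the contiguous True-run containing it.

    Works row-wise on a 2-D boolean array without crossing row boundaries.
    """
    above = np.atleast_2d(above)
    P, T = above.shape
    flat = above.ravel()
    starts = flat & ~np.concatenate([[False], flat[:-1]])
    # forbid runs crossing row boundaries
    row_start = np.zeros(P * T, dtype=bool)
    row_start[::T] = True
    starts |= flat & row_start
    run_id = np.cumsum(starts) * flat  # 0 where not above
    lengths = np.bincount(run_id, minlength=1)
    lengths[0] = 0
    return lengths[run_id].reshape(P, T)


def _tfce_signed(stat: np.ndarray, e: float, h: float, dh: float) -> np.ndarray:
    """TFCE of the positive part of ``stat``; rows are independent series."""
    stat = np.atleast_2d(stat)
    out = np.zeros_like(stat)
    top = stat.max()
    if top <= 0:
        return out
    heights = np.arange(dh, top + dh, dh)
    for ht in heights:
        above = stat >= ht
        if not above.any():
            break
        ext = _runs_extent(above)
        out += np.where(above, ext**e * ht**h * dh, 0.0)
    return out


def tfce(
    stat: np.ndarray,
    e: float = TFCE_E,
    h: float = TFCE_H,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D statistic series.

    For each time point the output integrates ``extent(h)^E * h^H`` over
    thresholds h from 0 up to the point's value (step ``dh``; default
    ``max |stat| / 100``).  Negative deflections are enhanced on the negated
    series and returned with negative sign.
    """
    stat = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite statistic")
    if dh is None:
        top = np.abs(stat).max()
        dh = top / 100.0 if top > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_signed(stat[None, :], e, h, dh)[0]
    neg = _tfce_signed(-stat[None, :], e, h, dh)[0]
    return pos - neg


def _t_one_sample(curves: np.ndarray) -> np.ndarray:
    n = curves.shape[0]
    m = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return m / (sd / np.sqrt(n))


def cluster_permutation(
    curves: np.ndarray,
    times: np.ndarray | None = None,
    baseline: tuple[float, float] | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    e: float = TFCE_E,
    h: float = TFCE_H,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """One-sample TFCE cluster permutation test on participant curves.

    ``curves`` is participants x time; for a paired contrast pass the
    per-participant difference curves (sign flips are then exactly
    condition-label swaps within participant).  If ``baseline`` is given,
    each participant's mean over that time window is subtracted first.  The
    null distribution is the maximum absolute enhanced value under random
    sign flips of whole participant curves; each observed supra-threshold
    cluster gets ``p = (1 + #{null >= cluster max}) / (n_perm + 1)``.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n, T = curves.shape
    if n < 5:
        raise ValueError("need at least five participants")
    if times is None:
        times = np.arange(T, dtype=float)
    times = np.asarray(times, dtype=float)
    if baseline is not None:
        sel = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9)
        if not sel.any():
            raise ValueError("empty baseline window")
        curves = curves - curves[:, sel].mean(axis=1, keepdims=True)

    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    t_obs = _t_one_sample(curves)
    top = np.abs(t_obs).max()
    dh = top / 100.0 if top > 0 else 1.0
    enhanced_obs = tfce(t_obs, e, h, dh)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs[:, :, None] * curves[None, :, :]
    m = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    t_null = m / (sd / np.sqrt(n))
    null_pos = _tfce_signed(t_null, e, h, dh)
    null_neg = _tfce_signed(-t_null, e, h, dh)
    null_max = np.maximum(null_pos.max(axis=1), null_neg.max(axis=1))

    thresh = float(np.quantile(null_max, 1.0 - alpha))
    abs_enh = np.abs(enhanced_obs)
    above = abs_enh > thresh
    clusters: list[Cluster] = []
    if above.any():
        edges = np.flatnonzero(
            np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
        )
        for s, t_end in zip(edges[::2], edges[1::2]):
            peak = abs_enh[s:t_end].max()
            p = (1.0 + np.sum(null_max >= peak)) / (n_perm + 1.0)
            clusters.append(
                Cluster(
                    t_start=float(times[s]),
                    t_end=float(times[t_end - 1]),
                    tfce_mass=float(abs_enh[s:t_end].sum()),
                    p_corrected=p,
                )
            )
    return ClusterResult(clusters, enhanced_obs, thresh, n_perm, seed)


def bonferroni(p_values, k: int):
    """Multiply p-values by the number of tests, capped at 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.minimum(1.0, np.asarray(p_values, dtype=float) * k)
    return float(p) if np.isscalar(p_values) else p


def cohens_d(diff_curves: np.ndarray) -> float:
    """Cohen's d of per-participant means over a cluster window.

    ``diff_curves`` is participants x window-samples; each participant is
    reduced to their window mean, and d = mean / sd of those values.
    """
    diff_curves = np.atleast_2d(np.asarray(diff_curves, dtype=float))
    if diff_curves.shape[0] < 2:
        raise ValueError("need at least two participants")
    per = diff_curves.mean(axis=1)
    sd = per.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across participants")
    return float(per.mean() / sd)
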
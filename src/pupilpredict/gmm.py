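"""Batched two-component Gaussian EM for sliding-window observers.

The fixed-window ideal observer refits a small mixture on every tone's
preceding window, and the context-window sweep multiplies that by ~47 window
sizes; a session involves hundreds of thousands of tiny fits.  This module
therefore runs EM *batched*: every window (x every random restart) is one row
of a masked matrix, rows are updated in lock-step, and converged rows are
compacted out of the working set.

Model: K=2 Gaussians, maximum-likelihood fit, variance floored, restarts
seeded.  Windows with fewer than four points, or fits that collapse, fall back
to a single Gaussian (second weight exactly 0).  The returned per-component
soft sufficient statistics (``counts``, ``xbar``, ``ss``) let callers layer a
conjugate posterior predictive on top of the point fit.
"""

from __future__ import annotations

import numpy as np

from .mixture import GRID_RES_OCT

__all__ = ["fit_gmm_batch", "VAR_FLOOR"]

#: variance floor: the variance of a uniform distribution over one grid bin
VAR_FLOOR = GRID_RES_OCT**2 / 12.0

_LOG2PI = float(np.log(2.0 * np.pi))
_MIN_POINTS = 4


def _single_component(x0: np.ndarray, mask: np.ndarray, var_floor: float):
    """Closed-form single-Gaussian fit per row; ``x0`` is zero where invalid."""
    n = np.maximum(mask.sum(axis=1), 1)
    mu = x0.sum(axis=1) / n
    ss = (np.where(mask, x0 - mu[:, None], 0.0) ** 2).sum(axis=1)
    var = np.maximum(ss / n, var_floor)
    ll = -0.5 * (n * (_LOG2PI + np.log(var)) + ss / var)
    return mu, var, ss, ll


def fit_gmm_batch(
    x: np.ndarray,
    mask: np.ndarray | None = None,
    n_restarts: int = 5,
    var_floor: float = VAR_FLOOR,
    tol: float = 1e-8,
    max_iter: int = 300,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Fit a 2-component GMM to every row of ``x``.

    Parameters
    ----------
    x : (B, L) array of observations; entries where ``mask`` is False (or
        ``x`` is NaN) are ignored.
    n_restarts : seeded random restarts per row; best log-likelihood wins.
    var_floor : lower bound on component variances (octaves^2).
    tol : absolute convergence tolerance on the row log-likelihood.

    Returns
    -------
    dict with per-row arrays: ``weights``, ``means``, ``vars``, ``counts``
    (soft counts), ``xbar`` (soft component means), ``ss`` (soft centered
    sums of squares), each (B, 2), and ``loglik`` (B,).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    B, L = x.shape
    if mask is None:
        mask = np.isfinite(x)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(np.where(mask, x, 0.0))
    counts_row = mask.sum(axis=1)
    if np.any(counts_row == 0):
        raise ValueError("empty window in GMM batch")
    x0_full = np.where(mask, x, 0.0)

    out = {
        "weights": np.zeros((B, 2)),
        "means": np.zeros((B, 2)),
        "vars": np.full((B, 2), var_floor),
        "counts": np.zeros((B, 2)),
        "xbar": np.zeros((B, 2)),
        "ss": np.zeros((B, 2)),
        "loglik": np.full(B, -np.inf),
    }

    def _store_single(rows: np.ndarray) -> None:
        mu, var, ss, ll = _single_component(x0_full[rows], mask[rows], var_floor)
        out["weights"][rows] = [1.0, 0.0]
        out["means"][rows] = mu[:, None]
        out["vars"][rows, 0] = var
        out["vars"][rows, 1] = var_floor
        out["counts"][rows, 0] = counts_row[rows]
        out["xbar"][rows] = mu[:, None]
        out["ss"][rows, 0] = ss
        out["loglik"][rows] = ll

    fb = counts_row < _MIN_POINTS
    if fb.any():
        _store_single(np.flatnonzero(fb))
    em_rows = np.flatnonzero(~fb)
    if em_rows.size == 0:
        return out

    # replicate rows per restart
    X = np.repeat(x0_full[em_rows], n_restarts, axis=0)
    M = np.repeat(mask[em_rows], n_restarts, axis=0)
    R = X.shape[0]
    N = M.sum(axis=1).astype(float)

    # init: two distinct valid points as means, pooled (floored) variance
    rng = np.random.default_rng(seed)
    u = rng.random((R, L))
    u[~M] = -1.0
    order = np.argsort(u, axis=1)
    mu = np.stack(
        [X[np.arange(R), order[:, -1]], X[np.arange(R), order[:, -2]]], axis=1
    )
    xbar0 = X.sum(axis=1) / N
    v0 = (np.where(M, X - xbar0[:, None], 0.0) ** 2).sum(axis=1) / N
    var = np.maximum(v0, var_floor)[:, None].repeat(2, axis=1)
    w = np.full((R, 2), 0.5)

    # working set: converged rows are compacted out
    idx = np.arange(R)
    final = {
        "w": np.empty((R, 2)),
        "mu": np.empty((R, 2)),
        "var": np.empty((R, 2)),
        "nk": np.empty((R, 2)),
        "xb": np.empty((R, 2)),
        "ss": np.empty((R, 2)),
        "ll": np.full(R, -np.inf),
    }

    def _flush(sel: np.ndarray, lj0, lj1, lse, ll) -> None:
        """Finalize rows ``sel`` (positions in the working set)."""
        rows = idx[sel]
        r1 = np.exp(lj1[sel] - lse[sel])
        r1[~M[rows]] = 0.0
        r0 = M[rows] - r1
        nk = np.stack([r0.sum(axis=1), r1.sum(axis=1)], axis=1)
        nks = np.maximum(nk, 1e-12)
        xb = np.stack(
            [(r0 * X[rows]).sum(axis=1), (r1 * X[rows]).sum(axis=1)], axis=1
        ) / nks
        ss = np.stack(
            [
                (r0 * (X[rows] - xb[:, 0:1]) ** 2 * M[rows]).sum(axis=1),
                (r1 * (X[rows] - xb[:, 1:2]) ** 2 * M[rows]).sum(axis=1),
            ],
            axis=1,
        )
        final["w"][rows] = w[sel]
        final["mu"][rows] = mu[sel]
        final["var"][rows] = var[sel]
        final["nk"][rows] = nk
        final["xb"][rows] = xb
        final["ss"][rows] = ss
        final["ll"][rows] = ll[sel]

    ll_prev = np.full(R, np.inf)
    Xa, Ma = X, M
    for it in range(max_iter):
        logw = np.log(np.maximum(w, 1e-300))
        lj0 = (
            logw[:, 0:1]
            - 0.5 * (_LOG2PI + np.log(var[:, 0:1]))
            - (Xa - mu[:, 0:1]) ** 2 / (2.0 * var[:, 0:1])
        )
        lj1 = (
            logw[:, 1:2]
            - 0.5 * (_LOG2PI + np.log(var[:, 1:2]))
            - (Xa - mu[:, 1:2]) ** 2 / (2.0 * var[:, 1:2])
        )
        lse = np.logaddexp(lj0, lj1)
        ll = np.where(Ma, lse, 0.0).sum(axis=1)

        done = np.abs(ll - ll_prev) < tol
        if it == max_iter - 1:
            done[:] = True
        if done.any():
            _flush(done, lj0, lj1, lse, ll)
            keep = ~done
            if not keep.any():
                break
            idx = idx[keep]
            w, mu, var, ll = w[keep], mu[keep], var[keep], ll[keep]
            lj0, lj1, lse = lj0[keep], lj1[keep], lse[keep]
            Xa, Ma = X[idx], M[idx]
        ll_prev = ll
        r1 = np.exp(lj1 - lse)
        r1[~Ma] = 0.0
        r0 = Ma - r1
        n0 = r0.sum(axis=1)
        n1 = r1.sum(axis=1)
        n0s = np.maximum(n0, 1e-12)
        n1s = np.maximum(n1, 1e-12)
        w = np.stack([n0, n1], axis=1) / (n0 + n1)[:, None]
        mu0 = (r0 * Xa).sum(axis=1) / n0s
        mu1 = (r1 * Xa).sum(axis=1) / n1s
        dead0 = n0 < 1e-10
        dead1 = n1 < 1e-10
        mu0 = np.where(dead0, mu[:, 0], mu0)
        mu1 = np.where(dead1, mu[:, 1], mu1)
        v0_ = (r0 * (Xa - mu0[:, None]) ** 2).sum(axis=1) / n0s
        v1_ = (r1 * (Xa - mu1[:, None]) ** 2).sum(axis=1) / n1s
        v0_ = np.where(dead0, var[:, 0], v0_)
        v1_ = np.where(dead1, var[:, 1], v1_)
        mu = np.stack([mu0, mu1], axis=1)
        var = np.maximum(np.stack([v0_, v1_], axis=1), var_floor)

    # pick the best restart per original row
    llr = final["ll"].reshape(-1, n_restarts)
    best = llr.argmax(axis=1)
    pick = np.arange(len(em_rows)) * n_restarts + best
    ll_b = llr[np.arange(len(em_rows)), best]
    w_b = final["w"][pick]

    # collapsed fits: vanished weight, non-finite params, or two components
    # that converged onto the same point (degenerate duplicate)
    duplicate = (
        np.abs(final["mu"][pick][:, 0] - final["mu"][pick][:, 1]) < 1e-8
    ) & (np.abs(final["var"][pick][:, 0] - final["var"][pick][:, 1]) < 1e-12)
    bad = (
        ~np.isfinite(ll_b)
        | ~np.isfinite(w_b).all(axis=1)
        | (w_b.min(axis=1) < 1e-9)
        | duplicate
    )
    good = ~bad
    rows = em_rows[good]
    gp = pick[good]
    out["weights"][rows] = final["w"][gp]
    out["means"][rows] = final["mu"][gp]
    out["vars"][rows] = final["var"][gp]
    out["counts"][rows] = final["nk"][gp]
    out["xbar"][rows] = final["xb"][gp]
    out["ss"][rows] = final["ss"][gp]
    out["loglik"][rows] = ll_b[good]
    if bad.any():
        _store_single(em_rows[bad])
    return out
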
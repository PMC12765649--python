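"""FIR/TRF estimation: design structure, OLS identities, cross-validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilpredict import trf
from pupilpredict.trf import (
    N_LAGS,
    EventSeries,
    build_design_matrix,
    choose_folds,
    crossval_trf,
    lag_grid,
    normalize_regressor,
    ols_trf,
    zscore_trial,
)


def single_regressor_events(onsets, values, n_samples):
    return EventSeries(np.asarray(onsets), {"s": np.asarray(values)}, n_samples)


class TestZscore:
    def test_standardizes(self):
        z = zscore_trial(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_constant_trial_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            z = zscore_trial(np.full(10, 3.0))
        assert np.all(z == 0)

    def test_idempotent_on_standardized(self, rng):
        y = rng.normal(size=500)
        y = (y - y.mean()) / y.std()
        np.testing.assert_allclose(zscore_trial(y), y, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zscore_trial(np.array([]))


class TestNormalizeRegressor:
    def test_endpoints_and_midpoint(self):
        v = normalize_regressor(np.array([1.0, 3.0, 2.0]), 1.0, 3.0)
        np.testing.assert_allclose(v, [0.0, 1.0, 0.5])

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            normalize_regressor(np.array([1.0]), 2.0, 2.0)

    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0.1, 5))
    @settings(max_examples=100, derandomize=True)
    def test_always_in_unit_interval(self, v, lo, width):
        out = normalize_regressor(np.array([v]), lo, lo + width)
        assert 0.0 <= out[0] <= 1.0


class TestDesignMatrix:
    def test_lag_count(self):
        assert N_LAGS == 181
        assert lag_grid()[0] == pytest.approx(-0.5)
        assert lag_grid()[-1] == pytest.approx(4.0)

    def test_single_impulse_traces_identity_band(self):
        ev = single_regressor_events([100], [1.0], 400)
        M, names = build_design_matrix([ev], center=False)
        lag_samp = np.round(lag_grid() * trf.FS).astype(int)
        for li, ls in enumerate(lag_samp):
            row = 100 + ls
            if 0 <= row < 400:
                assert M[row, li] == 1.0
        assert M.sum() == sum(1 for ls in lag_samp if 0 <= 100 + ls < 400)

    def test_no_leakage_across_trials(self):
        ev1 = single_regressor_events([390], [1.0], 400)  # spills past trial end
        ev2 = single_regressor_events([5], [1.0], 400)
        M, _ = build_design_matrix([ev1, ev2], center=False)
        # rows belonging to trial 2 must contain only trial-2 contributions
        block2 = M[400:]
        expected_nnz = np.count_nonzero(
            build_design_matrix([ev2], center=False)[0]
        )
        assert np.count_nonzero(block2) == expected_nnz

    def test_onset_outside_trial_rejected(self):
        with pytest.raises(ValueError):
            single_regressor_events([500], [1.0], 400)


class TestOls:
    def test_exact_recovery_without_noise(self, rng):
        M = rng.normal(size=(800, 2 * N_LAGS))
        beta = rng.normal(size=2 * N_LAGS)
        est = ols_trf(M, M @ beta, ["a", "b"])
        got = np.concatenate([est.coefficients["a"], est.coefficients["b"]])
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_orthogonal_noise_gives_zero(self, rng):
        M = rng.normal(size=(600, N_LAGS))
        noise = rng.normal(size=600)
        noise -= M @ np.linalg.lstsq(M, noise, rcond=None)[0]
        est = ols_trf(M, noise, ["a"])
        np.testing.assert_allclose(est.coefficients["a"], 0.0, atol=1e-8)

    def test_orthogonal_regressors_separable(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(800, 2 * N_LAGS)))
        M = q
        y = rng.normal(size=800)
        joint = ols_trf(M, y, ["a", "b"])
        a_only = ols_trf(M[:, :N_LAGS], y, ["a"])
        np.testing.assert_allclose(
            joint.coefficients["a"], a_only.coefficients["a"], atol=1e-8
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ols_trf(np.zeros((10, N_LAGS)), np.zeros(11), ["a"])


class TestChooseFolds:
    @pytest.mark.parametrize(
        "n, k, discard", [(48, 8, 0), (50, 8, 2), (64, 8, 0), (63, 8, 7), (46, 8, 6)]
    )
    def test_preference_order(self, n, k, discard):
        assert choose_folds(n) == (k, discard)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            choose_folds(5)


def _simulate_trials(rng, n_trials, kernel, noise_sd, n_samples=600):
    """Trials with 30 tones at fixed spacing, values in [0, 1]."""
    events, ys = [], []
    lag_samp = np.round(lag_grid() * trf.FS).astype(int)
    for _ in range(n_trials):
        onsets = 30 + np.arange(30) * 10
        vals = rng.uniform(0, 1, 30)
        ev = single_regressor_events(onsets, vals, n_samples)
        y = np.zeros(n_samples)
        for o, v in zip(onsets, vals):
            rows = o + lag_samp
            ok = (rows >= 0) & (rows < n_samples)
            y[rows[ok]] += v * kernel[ok]
        y = y - y.mean()
        if noise_sd:
            y = y + noise_sd * rng.normal(size=n_samples)
        events.append(ev)
        ys.append(y)
    return events, ys


class TestCrossval:
    def kernel(self):
        lags = lag_grid()
        k = np.where(lags > 0, (lags / 0.9) ** 3 * np.exp(3 * (1 - lags / 0.9)), 0.0)
        return k

    def test_noiseless_recovery_is_exact(self, rng):
        k = self.kernel()
        events, ys = _simulate_trials(rng, 12, k, 0.0)
        _, mean_trf, report = crossval_trf(events, ys, rng=0)
        r = np.corrcoef(mean_trf.coefficients["s"], k)[0, 1]
        assert r > 0.9999
        assert min(report["heldout_r2"]) > 0.999

    def test_noise_shrinks_but_preserves_shape(self, rng):
        k = self.kernel()
        events, ys = _simulate_trials(rng, 40, k, 1.0)
        _, mean_trf, _ = crossval_trf(events, ys, rng=0)
        assert np.corrcoef(mean_trf.coefficients["s"], k)[0, 1] > 0.8

    def test_pure_noise_heldout_r2_not_optimistic(self):
        """Held-out R^2 on noise-only targets centers at or below zero."""
        r2 = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            events, ys = _simulate_trials(rng, 8, np.zeros(N_LAGS), 1.0, 400)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, report = crossval_trf(events, ys, rng=seed)
            r2.extend(report["heldout_r2"])
        assert np.mean(r2) <= 0.0

    def test_permuted_values_destroy_recovery(self, rng):
        k = self.kernel()
        events, ys = _simulate_trials(rng, 20, k, 0.2)
        shuffled = [
            EventSeries(
                ev.onsets, {"s": rng.permutation(ev.values["s"])}, ev.n_samples
            )
            for ev in events
        ]
        _, good, rep_good = crossval_trf(events, ys, rng=0)
        _, bad, rep_bad = crossval_trf(shuffled, ys, rng=0)
        r_good = np.corrcoef(good.coefficients["s"], k)[0, 1]
        assert r_good > 0.95
        # the value-independent (mean) response survives permutation, but the
        # value-driven part of the fit collapses: held-out unexplained
        # variance explodes relative to the intact regressor
        unexplained_good = 1.0 - np.mean(rep_good["heldout_r2"])
        unexplained_bad = 1.0 - np.mean(rep_bad["heldout_r2"])
        assert unexplained_bad > 3.0 * unexplained_good

    def test_too_few_trials_rejected(self, rng):
        events, ys = _simulate_trials(rng, 5, np.zeros(N_LAGS), 1.0, 400)
        with pytest.raises(ValueError):
            crossval_trf(events, ys, rng=0)
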
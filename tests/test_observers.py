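"""Observer models: run-length filter dynamics, ideal observer, window sweep."""

import numpy as np
import pytest
from scipy.stats import t as student_t

from pupilpredict import stimgen
from pupilpredict.mixture import mixture_precision
from pupilpredict.observers import (
    DrexState,
    ObserverConfig,
    ObserverTrace,
    drex_step,
    drex_trace,
    ideal_observer_trace,
    optimize_context_window,
    regressor_statistics,
)

CENTERS = (0.4, 2.2)


def resolved_cfg(**kw):
    return ObserverConfig(**kw).resolved()


class TestDrexStep:
    def test_learning_reduces_surprisal_on_constant_input(self):
        cfg = resolved_cfg()
        state = DrexState.initial()
        surprisals = []
        for _ in range(30):
            state, _, s, _ = drex_step(state, 0.0, cfg)
            surprisals.append(s)
        assert surprisals[29] < surprisals[1]

    def test_beliefs_and_weights_stay_normalized(self, rng):
        cfg = resolved_cfg()
        state = DrexState.initial()
        for _ in range(40):
            x = float(rng.normal(1.0, 0.8))
            state, mix, s, p = drex_step(state, x, cfg)
            assert state.belief.sum() == pytest.approx(1.0, abs=1e-9)
            assert mix.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert s >= 0.0
            assert p > 0.0

    def test_zero_hazard_never_reallocates_to_fresh_hypothesis(self):
        cfg = resolved_cfg(hazard=0.0)
        state = DrexState.initial()
        for x in (0.1, 0.2, 0.15, 0.12):
            state, *_ = drex_step(state, x, cfg)
        assert state.belief[0] == 0.0
        assert state.belief[-1] == pytest.approx(1.0)

    def test_exported_mixture_consistent_with_precision(self):
        cfg = resolved_cfg()
        state = DrexState.initial()
        for x in (0.3, 0.5, 0.4):
            state, mix, _, precision = drex_step(state, x, cfg)
            assert mixture_precision(mix) == pytest.approx(precision, rel=1e-9)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            drex_step(DrexState.initial(), np.nan, resolved_cfg())

    def test_matches_bruteforce_conjugate_update(self):
        """Oracle: hazard 0, one component == direct NIG Student-t scoring."""
        cfg = resolved_cfg(hazard=0.0, max_components=1)
        xs = [0.25, 0.4, 0.3, 0.55, 0.35]
        state = DrexState.initial()
        got = []
        for x in xs:
            state, _, s, _ = drex_step(state, x, cfg)
            got.append(s)

        k0, a0, b0, mu0 = cfg.kappa0, cfg.alpha0, cfg.beta0, cfg.prior_mean
        expected = []
        for t_idx, x in enumerate(xs):
            data = np.array(xs[:t_idx])
            n = len(data)
            xbar = data.mean() if n else 0.0
            ss = ((data - xbar) ** 2).sum() if n else 0.0
            kn = k0 + n
            an = a0 + n / 2
            bn = b0 + ss / 2 + k0 * n * (xbar - mu0) ** 2 / (2 * kn)
            scale = np.sqrt(bn * (kn + 1) / (an * kn))
            nu = 2 * an
            p = student_t.cdf((x + 1 / 24 - ((k0 * mu0 + n * xbar) / kn)) / scale, nu) - \
                student_t.cdf((x - 1 / 24 - ((k0 * mu0 + n * xbar) / kn)) / scale, nu)
            expected.append(-np.log(p))
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestDrexTrace:
    def test_deterministic(self, small_session):
        tr = small_session.trials[0]
        a = drex_trace(tr, resolved_cfg())
        b = drex_trace(tr, resolved_cfg())
        np.testing.assert_array_equal(a.surprisal, b.surprisal)
        np.testing.assert_array_equal(a.precision, b.precision)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            drex_trace([], resolved_cfg())

    def test_precision_increases_in_unambiguous_context(self):
        """Narrow single-source input: precision rises monotonically.

        With one source and a near-degenerate spread there are no outlier
        tones to open a second component, so accumulating evidence must
        sharpen the predictive landscape tone by tone.
        """
        rng = np.random.default_rng(0)
        cfg = resolved_cfg()
        x = np.round(rng.normal(1.0, 1e-3, 20) * 12) / 12
        trace = drex_trace(x, cfg)
        assert np.all(np.diff(trace.precision[:10]) > 0)

    def test_precision_grows_within_low_entropy_segments_on_average(self):
        """Across 100 seeded low-entropy trials, later tones are on average
        more precise than early ones (per-trial drops can occur when the
        minority source is first discovered)."""
        rng = np.random.default_rng(0)
        cfg = resolved_cfg()
        early, late = [], []
        for _ in range(100):
            tr = stimgen.generate_trial("LE-LE", rng, CENTERS)
            trace = drex_trace(tr, cfg)
            early.append(trace.precision[1:5].mean())
            late.append(trace.precision[10:20].mean())
        assert np.mean(late) > np.mean(early)

    def test_narrow_context_more_precise_than_broad(self):
        rng = np.random.default_rng(1)
        cfg = resolved_cfg()
        le = np.mean(
            [
                drex_trace(stimgen.generate_trial("LE-LE", rng, CENTERS), cfg).precision.mean()
                for _ in range(20)
            ]
        )
        he = np.mean(
            [
                drex_trace(stimgen.generate_trial("HE-HE", rng, CENTERS), cfg).precision.mean()
                for _ in range(20)
            ]
        )
        assert le > he

    def test_surprisal_precision_negatively_correlated(self, small_session_traces):
        stats = regressor_statistics(small_session_traces)
        assert stats["surprisal_precision_r"] < 0

    def test_memory_truncation_bounds_hypothesis_count(self):
        cfg = resolved_cfg(memory_m=10)
        state = DrexState.initial()
        rng = np.random.default_rng(2)
        for _ in range(30):
            state, *_ = drex_step(state, float(rng.normal()), cfg)
        assert state.n_hypotheses == 11
        assert state.belief.sum() == pytest.approx(1.0, abs=1e-9)


class TestIdealObserver:
    def test_first_tone_uniform_prior(self):
        cfg = resolved_cfg()
        trace = ideal_observer_trace(np.array([0.5, 0.5, 0.5]), cfg)
        grid = cfg.grid
        assert trace.surprisal[0] == pytest.approx(np.log(len(grid)))
        assert trace.precision[0] == pytest.approx(1.0 / np.var(grid))

    def test_constant_sequence_minimizes_late_surprisal(self):
        cfg = resolved_cfg()
        x = np.full(40, 1.0)
        trace = ideal_observer_trace(x, cfg)
        assert trace.surprisal[21] <= trace.surprisal[1:22].min() + 1e-9

    def test_surprisal_positive_precision_positive(self, small_session):
        trace = ideal_observer_trace(small_session.trials[0], resolved_cfg())
        assert np.all(trace.surprisal >= 0)
        assert np.all(trace.precision > 0)


class TestContextWindowSweep:
    def test_tiny_sequence_all_windows_tie_to_smallest(self):
        # a 4-tone sequence never fills any candidate window
        best = optimize_context_window([np.array([0.1, 0.2, 0.15, 0.3])], (4, 50))
        assert best == 4

    def test_longer_window_preferred_for_stationary_sequences(self, rng):
        seqs = [
            np.round(rng.normal(1.0, 0.5, 60) * 12) / 12 for _ in range(6)
        ]
        _, ll = optimize_context_window(
            seqs, (4, 12), return_loglik=True
        )
        assert ll[12] > ll[4]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            optimize_context_window([], (4, 50))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            optimize_context_window([np.zeros(10)], (10, 4))


class TestObserverTraceType:
    def test_negative_surprisal_rejected(self):
        with pytest.raises(ValueError):
            ObserverTrace([-0.1], [1.0])

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError):
            ObserverTrace([0.1], [0.0])
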
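"""Preprocessing chain: resampling, blink handling, filtering, exclusions."""

import numpy as np
import pytest

from pupilpredict.preprocess import (
    FS_INTERMEDIATE,
    FS_OUT,
    PupilTrace,
    RawGaze,
    blink_residualize,
    detect_blinks,
    exclude_participants,
    exclude_trials,
    filter_downsample,
    interpolate_gaps,
    preprocess_trace,
    regularize,
)


def make_raw(signal_fn, duration=20.0, fs=225.0, jitter=0.1, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    dt = (1 / fs) * (1 + jitter * rng.uniform(-1, 1, n))
    t = np.cumsum(dt) - dt[0]
    return RawGaze(t, signal_fn(t))


def trace125(y, t0=0.0):
    return PupilTrace(FS_INTERMEDIATE, y, np.zeros(len(y), dtype=bool), t0=t0)


class TestRegularize:
    def test_constant_preserved(self):
        raw = make_raw(lambda t: np.full_like(t, 5.0))
        out = regularize(raw)
        np.testing.assert_allclose(out.samples, 5.0, atol=1e-9)
        assert out.fs == FS_INTERMEDIATE

    def test_slow_sine_amplitude_preserved(self):
        raw = make_raw(lambda t: np.sin(2 * np.pi * 0.5 * t), duration=30.0)
        out = regularize(raw)
        mid = out.samples[125:-125]  # avoid edges
        assert abs(mid.max() - 1.0) < 0.01
        assert abs(mid.min() + 1.0) < 0.01

    def test_impulse_becomes_hanning_bump(self):
        raw = make_raw(lambda t: np.zeros_like(t), duration=4.0, jitter=0.0)
        y = raw.pupil_area.copy()
        y[len(y) // 2] = 1.0
        raw = RawGaze(raw.timestamps, y)
        out = regularize(raw)
        support = np.flatnonzero(np.abs(out.samples) > 1e-6)
        width_s = (support[-1] - support[0]) / out.fs
        assert width_s <= 0.20  # 150 ms window + grid effects

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            RawGaze([0.0, 0.1, 0.1], [1, 2, 3])


class TestDetectBlinks:
    def test_smooth_sine_clean(self):
        t = np.arange(0, 20, 1 / FS_INTERMEDIATE)
        tr = trace125(np.sin(2 * np.pi * 0.5 * t))
        assert detect_blinks(tr) == []

    def test_step_artifact_flagged_and_padded(self):
        t = np.arange(0, 20, 1 / FS_INTERMEDIATE)
        y = np.sin(2 * np.pi * 0.3 * t)
        step_at, width = 1000, 10  # 80 ms dip: edges merge into one segment
        y[step_at : step_at + width] -= 8.0
        segs = detect_blinks(trace125(y))
        assert len(segs) == 1
        s, e = segs[0]
        assert s <= step_at < e
        # extends at least 200 ms past the recovery edge
        assert e >= step_at + width + 0.2 * FS_INTERMEDIATE

    def test_nearby_artifacts_merged(self):
        t = np.arange(0, 20, 1 / FS_INTERMEDIATE)
        y = np.sin(2 * np.pi * 0.3 * t)
        y[1000:1005] -= 9.0
        gap = int(0.05 * FS_INTERMEDIATE)  # 50 ms apart
        y[1005 + gap : 1010 + gap] -= 9.0
        assert len(detect_blinks(trace125(y))) == 1


class TestInterpolateGaps:
    def test_no_segments_identity(self):
        tr = trace125(np.arange(100.0))
        out = interpolate_gaps(tr, [])
        assert out is tr

    def test_linear_ramp_filled_exactly(self):
        y = np.arange(200.0)
        out = interpolate_gaps(trace125(y.copy()), [(50, 80)])
        np.testing.assert_allclose(out.samples, y, atol=1e-8)
        assert out.interp_mask[50:80].all()

    def test_monotone_fill_has_no_overshoot(self, rng):
        y = np.sort(rng.uniform(0, 10, 300))
        out = interpolate_gaps(trace125(y.copy()), [(100, 140)])
        assert out.samples[100:140].min() >= y[99] - 1e-9
        assert out.samples[100:140].max() <= y[140] + 1e-9

    def test_edge_segment_nearest_fill(self):
        y = np.arange(100.0)
        out = interpolate_gaps(trace125(y.copy()), [(0, 10)])
        np.testing.assert_allclose(out.samples[:10], y[10])

    def test_out_of_extent_rejected(self):
        with pytest.raises(ValueError):
            interpolate_gaps(trace125(np.zeros(50)), [(40, 60)])


class TestFilterDownsample:
    def _gain(self, freq):
        t = np.arange(0, 60, 1 / FS_INTERMEDIATE)
        tr = trace125(np.sin(2 * np.pi * freq * t))
        out = filter_downsample(tr)
        mid = out.samples[len(out) // 4 : -len(out) // 4]
        return mid.std() * np.sqrt(2)

    def test_dc_removed(self):
        t = np.arange(0, 60, 1 / FS_INTERMEDIATE)
        out = filter_downsample(trace125(np.full(len(t), 5.0)))
        assert np.abs(out.samples.mean()) < 0.01

    def test_passband_unity_within_1db(self):
        assert abs(20 * np.log10(self._gain(1.0))) < 1.0

    def test_stopband_10hz_attenuated_20db(self):
        assert 20 * np.log10(self._gain(10.0)) < -20.0

    def test_output_rate(self):
        t = np.arange(0, 20, 1 / FS_INTERMEDIATE)
        out = filter_downsample(trace125(np.sin(t)))
        assert out.fs == FS_OUT

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            filter_downsample(trace125(np.zeros(100)))


class TestBlinkResidualize:
    def test_no_blinks_identity(self):
        tr = PupilTrace(FS_OUT, np.sin(np.arange(800) / 40), np.zeros(800, bool))
        out = blink_residualize(tr)
        assert out is tr

    def test_stereotyped_transients_removed(self):
        fs = FS_OUT
        n = int(60 * fs)
        kernel = np.sin(np.pi * np.arange(int(1.6 * fs)) / (1.6 * fs)) ** 2
        y = np.zeros(n)
        offsets = np.array([5.0, 12.0, 21.0, 33.0, 40.0, 51.0])
        for o in offsets:
            i = int(o * fs)
            y[i : i + len(kernel)] += kernel
        tr = PupilTrace(fs, y, np.zeros(n, bool), blink_offsets=offsets)
        out = blink_residualize(tr)
        assert np.std(out.samples) < 0.1 * np.std(y)

    def test_overlapping_transients_additive(self):
        fs = FS_OUT
        n = int(30 * fs)
        kernel = np.exp(-np.arange(int(1.6 * fs)) / 10.0)
        y = np.zeros(n)
        offsets = np.array([5.0, 5.5, 14.0])  # first two overlap
        for o in offsets:
            i = int(o * fs)
            y[i : i + len(kernel)] += kernel
        tr = PupilTrace(fs, y, np.zeros(n, bool), blink_offsets=offsets)
        out = blink_residualize(tr)
        # overlap biases the template estimate, so removal is partial but the
        # convolved regressor still handles superimposed transients linearly
        assert np.std(out.samples) < 0.5 * np.std(y)


class TestExclusions:
    def _trial(self, frac, gap_s, fs=40.0, n=780):
        mask = np.zeros(n, dtype=bool)
        gap_n = int(gap_s * fs)
        mask[:gap_n] = True
        extra = int(frac * n) - gap_n
        if extra > 0:
            # scattered singletons cannot extend the max run
            idx = np.arange(gap_n + 2, n, 3)[:extra]
            mask[idx] = True
        return PupilTrace(fs, np.zeros(n), mask), {}

    def test_below_both_thresholds_kept(self):
        kept, _ = exclude_trials([self._trial(0.34, 1.0)])
        assert kept == [0]

    def test_interpolation_fraction_threshold(self):
        kept, report = exclude_trials([self._trial(0.35, 1.0)])
        assert kept == []
        assert report["per_trial"][0]["kept"] is False

    def test_long_gap_threshold(self):
        kept, _ = exclude_trials([self._trial(0.10, 1.5)])
        assert kept == []

    def test_participant_trf_mode(self):
        sessions = {
            "p1": {"n_total": 144, "n_kept": 71},
            "p2": {"n_total": 144, "n_kept": 72},
        }
        kept, _ = exclude_participants(sessions, mode="trf")
        assert kept == ["p2"]  # 50.7% removed > 50%; exactly 50% is kept

    def test_participant_condition_mode(self):
        ok = {c: 13 for c in "abcde"}
        low = dict(ok, e=12)
        kept, _ = exclude_participants(
            {"p1": {"kept_by_condition": ok}, "p2": {"kept_by_condition": low}},
            mode="condition",
        )
        assert kept == ["p1"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            exclude_participants({}, mode="bogus")


class TestEndToEnd:
    def test_deterministic(self):
        raw = make_raw(lambda t: np.sin(2 * np.pi * 0.7 * t), seed=4)
        a = preprocess_trace(raw)
        b = preprocess_trace(raw)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_clean_bandlimited_signal_preserved(self):
        def sig(t):
            return (
                np.sin(2 * np.pi * 0.4 * t)
                + 0.5 * np.sin(2 * np.pi * 1.1 * t + 0.3)
                + 0.2 * np.sin(2 * np.pi * 2.3 * t + 1.1)
            )

        raw = make_raw(sig, duration=40.0, seed=5)
        out = preprocess_trace(raw)
        t_out = out.times
        sel = (t_out > 4.0) & (t_out < 36.0)  # filter edges excluded
        ref = sig(t_out[sel])
        ref = ref - ref.mean()
        got = out.samples[sel]
        r = np.corrcoef(got, ref)[0, 1]
        assert r >= 0.99

    def test_interp_fraction_consistent_across_rates(self):
        raw = make_raw(lambda t: np.sin(2 * np.pi * 0.5 * t), duration=30.0)
        y = raw.pupil_area.copy()
        y[2000:2300] -= 8.0  # artifact triggers interpolation
        raw = RawGaze(raw.timestamps, y)
        tr = regularize(raw)
        segs = detect_blinks(tr)
        tr = interpolate_gaps(tr, segs)
        frac125 = tr.interp_mask.mean()
        frac40 = filter_downsample(tr).interp_mask.mean()
        assert abs(frac125 - frac40) < 0.02
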
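"""Forward pupil simulator: ground-truth kernels to raw-gaze records.

Simulates what the eye tracker would record if the pupil responded to the
observer regressors through known lag kernels: tone impulses scaled by the
normalized surprisal/precision values are convolved with gamma-shaped
kernels, an optional boundary kernel is added per condition, pink (1/f)
noise models slow pupil drift, and blinks appear as deleted samples flanked
by sharp partial-closure ramps plus a stereotyped post-blink recovery
transient.  Records are emitted at irregular ~225 Hz timestamps so the whole
preprocessing chain is exercised, and every stage downstream can be checked
by parameter recovery against the known kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from . import preprocess, stimgen, trf
from .observers import ObserverConfig, ObserverTrace, session_traces
from .preprocess import RawGaze
from .trf import EventSeries, normalize_regressor

__all__ = [
    "GroundTruthKernel",
    "SimConfig",
    "make_gamma_kernel",
    "default_kernels",
    "simulate_participant",
    "build_event_series",
    "crop_trace",
    "recovery_experiment",
    "RAW_EPOCH_S",
    "TRIAL_EPOCH_S",
]

#: raw simulation epoch and the analysis epoch cropped from it (s, re trial onset)
RAW_EPOCH_S = (-1.5, 20.0)
TRIAL_EPOCH_S = (-0.5, 19.0)

FS_RAW = 225.0


@dataclass
class GroundTruthKernel:
    """A lag-resolved impulse response on the 40 Hz lag grid."""

    lags: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.lags.shape != self.amplitudes.shape:
            raise ValueError("kernel lag/amplitude shape mismatch")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("non-finite kernel")

    def resample(self, fs: float) -> np.ndarray:
        t = np.arange(0.0, self.lags[-1] + 1.0 / fs, 1.0 / fs)
        return np.interp(t, self.lags, self.amplitudes)


@dataclass
class SimConfig:
    """Synthetic-recording conditions.

    noise_sd=None calibrates the pink-noise sd per trial to the clean
    signal's sd (trial-level SNR of about 0 dB); kernel amplitudes vary
    +/- ``kernel_jitter`` across participants.
    """

    pink_exponent: float = 1.0
    noise_sd: float | None = None
    blink_rate_hz: float = 0.1
    blink_duration_s: tuple[float, float] = (0.1, 0.3)
    n_participants: int = 24
    kernel_jitter: float = 0.2
    fs_raw: float = FS_RAW
    timestamp_jitter: float = 0.1    # fractional jitter of the raw sampling step
    baseline_area: float = 800.0
    gain: float = 100.0

    def __post_init__(self) -> None:
        if self.blink_rate_hz < 0 or self.kernel_jitter < 0:
            raise ValueError("rates must be non-negative")


def make_gamma_kernel(
    peak_s: float,
    amplitude: float,
    shape: float = 6.0,
    fs: float = trf.FS,
    t_max: float = trf.LAG_MAX_S,
) -> GroundTruthKernel:
    """Gamma-shaped pupil impulse response peaking at ``peak_s``.

    ``k(t) = amplitude * (t / peak)^shape * exp(shape * (1 - t / peak))`` —
    zero at lag 0, unimodal, and (for the default shape) below 1% of peak by
    4 s for peaks up to about 1.5 s.
    """
    if not 0.0 < peak_s < t_max:
        raise ValueError("peak must lie inside the lag window")
    t = np.arange(0.0, t_max + 1.0 / fs, 1.0 / fs)
    x = t / peak_s
    k = amplitude * x**shape * np.exp(shape * (1.0 - x))
    return GroundTruthKernel(t, k)


def default_kernels() -> dict[str, GroundTruthKernel]:
    """Ground-truth kernels emulating reported pupil dynamics.

    Surprisal: sustained dilation peaking mid-window; precision: earlier,
    smaller response; boundary (only in the distinct-low-entropy transition):
    late dilation emulating a context-shift response.
    """
    return {
        "surprisal": make_gamma_kernel(1.5, 1.0),
        "precision": make_gamma_kernel(0.8, 0.6),
        "boundary:LE-dLE": make_gamma_kernel(2.2, 0.8, shape=4.0),
    }


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec *= freqs ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _regressor_bounds(
    traces: Sequence[ObserverTrace],
) -> dict[str, tuple[float, float]]:
    bounds = {}
    for name in ("surprisal", "precision"):
        allv = np.concatenate([getattr(t, name) for t in traces])
        bounds[name] = (float(allv.min()), float(allv.max()))
    return bounds


def build_event_series(
    session: stimgen.Session,
    traces: Sequence[ObserverTrace],
    fs: float = trf.FS,
    epoch_s: tuple[float, float] = TRIAL_EPOCH_S,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[EventSeries]:
    """Per-trial tone events with session-normalized regressor values."""
    bounds = bounds or _regressor_bounds(traces)
    n_samples = int(round((epoch_s[1] - epoch_s[0]) * fs))
    out = []
    for tr, obs in zip(session.trials, traces):
        onsets = np.round((tr.onsets - epoch_s[0]) * fs).astype(int)
        values = {
            name: normalize_regressor(getattr(obs, name), *bounds[name])
            for name in ("surprisal", "precision")
        }
        out.append(EventSeries(onsets, values, n_samples))
    return out


def _clean_signal(
    tr: stimgen.ToneSequence,
    obs: ObserverTrace,
    kernels: dict[str, GroundTruthKernel],
    bounds: dict[str, tuple[float, float]],
    fs: float,
    epoch_s: tuple[float, float],
) -> np.ndarray:
    n = int(round((epoch_s[1] - epoch_s[0]) * fs))
    y = np.zeros(n)
    onset_idx = np.round((tr.onsets - epoch_s[0]) * fs).astype(int)
    for name in ("surprisal", "precision"):
        if name not in kernels:
            continue
        vals = normalize_regressor(getattr(obs, name), *bounds[name])
        impulses = np.zeros(n)
        impulses[onset_idx] = vals
        y += sp_signal.fftconvolve(impulses, kernels[name].resample(fs))[:n]
    bkey = f"boundary:{tr.condition}"
    if bkey in kernels:
        impulses = np.zeros(n)
        impulses[onset_idx[tr.boundary_idx]] = 1.0
        y += sp_signal.fftconvolve(impulses, kernels[bkey].resample(fs))[:n]
    return y


def simulate_participant(
    session: stimgen.Session,
    observer_traces: Sequence[ObserverTrace],
    kernels: dict[str, GroundTruthKernel],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[RawGaze]:
    """One participant's raw-gaze records, one per trial."""
    fs = cfg.fs_raw
    epoch = RAW_EPOCH_S
    bounds = _regressor_bounds(observer_traces)
    out = []
    for tr, obs in zip(session.trials, observer_traces):
        clean = _clean_signal(tr, obs, kernels, bounds, fs, epoch)
        sd_clean = clean.std()
        noise_sd = cfg.noise_sd if cfg.noise_sd is not None else sd_clean
        y = clean + noise_sd * _pink_noise(len(clean), cfg.pink_exponent, rng)

        # irregular, strictly increasing timestamps around the nominal rate
        dt = (1.0 / fs) * (
            1.0 + cfg.timestamp_jitter * rng.uniform(-1.0, 1.0, size=len(y))
        )
        t = epoch[0] + np.cumsum(dt) - dt[0]

        keep = np.ones(len(y), dtype=bool)
        duration = epoch[1] - epoch[0]
        n_blinks = rng.poisson(cfg.blink_rate_hz * duration)
        for _ in range(n_blinks):
            b0 = rng.uniform(epoch[0] + 1.0, epoch[1] - 3.0)
            b1 = b0 + rng.uniform(*cfg.blink_duration_s)
            gap = (t >= b0) & (t < b1)
            keep &= ~gap
            # partial-closure ramp just before the gap, recapture dip after
            pre = (t >= b0 - 0.04) & (t < b0)
            post = (t >= b1) & (t < b1 + 0.08)
            y[pre] -= np.linspace(0.0, 4.0, pre.sum())
            y[post] -= np.linspace(4.0, 0.0, post.sum())
            # stereotyped post-blink recovery over 1.6 s
            rec = (t >= b1) & (t < b1 + 1.6)
            tr_rel = (t[rec] - b1) / 1.6
            y[rec] += 1.5 * np.sin(np.pi * tr_rel) ** 2
        out.append(
            RawGaze(
                timestamps=t[keep],
                pupil_area=cfg.baseline_area + cfg.gain * y[keep],
                valid=np.ones(keep.sum(), dtype=bool),
            )
        )
    return out


def crop_trace(
    trace: preprocess.PupilTrace,
    epoch_s: tuple[float, float] = TRIAL_EPOCH_S,
) -> preprocess.PupilTrace:
    """Crop a preprocessed trace to the analysis epoch (re trial onset)."""
    n = int(round((epoch_s[1] - epoch_s[0]) * trace.fs))
    i0 = int(round((epoch_s[0] - trace.t0) * trace.fs))
    if i0 < 0 or i0 + n > len(trace):
        raise ValueError("trace does not cover the analysis epoch")
    return replace(
        trace,
        samples=trace.samples[i0 : i0 + n],
        interp_mask=trace.interp_mask[i0 : i0 + n],
        t0=epoch_s[0],
    )


def _jittered_kernels(
    kernels: dict[str, GroundTruthKernel], jitter: float, rng: np.random.Generator
) -> dict[str, GroundTruthKernel]:
    out = {}
    for name, k in kernels.items():
        scale = 1.0 + jitter * rng.uniform(-1.0, 1.0)
        out[name] = GroundTruthKernel(k.lags, scale * k.amplitudes)
    return out


def recovery_experiment(
    cfg: SimConfig | None = None,
    n_trials: int = 120,
    session_seed: int = 0,
    observer_cfg: ObserverConfig | None = None,
    kernels: dict[str, GroundTruthKernel] | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """End-to-end parameter recovery: simulate, preprocess, fit, compare.

    For each simulated participant the pipeline runs preprocess ->
    cross-validated TRF; the report gives the per-regressor correlation and
    RMSE between estimated TRFs and the participant's ground-truth kernels,
    plus the group TRF curves for downstream cluster testing.
    """
    cfg = cfg or SimConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_blocks = max(1, n_trials // 16)
    sess_cfg = stimgen.SessionConfig(
        n_blocks=n_blocks, trials_per_block=max(1, n_trials // n_blocks)
    )
    session = stimgen.generate_session(sess_cfg, np.random.default_rng(session_seed))
    traces = session_traces(session, observer_cfg, model="drex")
    base_kernels = kernels or default_kernels()
    events = build_event_series(session, traces)
    lag_sel = trf.lag_grid() >= 0  # kernels live on non-negative lags

    per_participant = []
    trf_curves = {"surprisal": [], "precision": []}
    for p in range(cfg.n_participants):
        pk = _jittered_kernels(base_kernels, cfg.kernel_jitter, rng)
        raw = simulate_participant(session, traces, pk, cfg, rng)
        y_trials = []
        for r in raw:
            trace = crop_trace(preprocess.preprocess_trace(r))
            y_trials.append(trf.zscore_trial(trace.samples))
        _, mean_trf, report = trf.crossval_trf(events, y_trials, rng=rng)
        row = {"participant": p, "heldout_r2": report["heldout_r2"]}
        for name in ("surprisal", "precision"):
            est = mean_trf.coefficients[name][lag_sel]
            true = pk[name].resample(trf.FS)[: lag_sel.sum()]
            r = float(np.corrcoef(est, true)[0, 1])
            scale = float(est @ true / (true @ true)) if true.any() else np.nan
            row[f"corr_{name}"] = r
            row[f"rmse_{name}"] = float(
                np.sqrt(np.mean((est / max(scale, 1e-12) - true) ** 2))
            )
            row[f"scale_{name}"] = scale
            trf_curves[name].append(mean_trf.coefficients[name])
        per_participant.append(row)

    report = {
        "n_participants": cfg.n_participants,
        "n_trials": len(session),
        "per_participant": per_participant,
        "mean_corr": {
            name: float(np.mean([r[f"corr_{name}"] for r in per_participant]))
            for name in ("surprisal", "precision")
        },
        "trf_curves": {k: np.vstack(v) for k, v in trf_curves.items()},
        "lags": trf.lag_grid(),
    }
    return report
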
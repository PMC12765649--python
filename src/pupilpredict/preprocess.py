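"""Pupillometry preprocessing: raw gaze records to clean 40 Hz traces.

The chain mirrors standard pupil pipelines: time-accurate resampling of the
irregular (~225 Hz) eye-tracker stream to 125 Hz with 150-ms Hanning
smoothing; blink/artifact detection on the z-scored first difference;
shape-preserving (PCHIP) gap interpolation; anti-aliased decimation to 40 Hz
followed by a zero-phase 0.1-4 Hz band-pass; and regression-based removal of
the stereotyped post-blink recovery transient.  Trial and participant
exclusion rules operate on the interpolation bookkeeping carried through the
chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "RawGaze",
    "PupilTrace",
    "regularize",
    "detect_blinks",
    "interpolate_gaps",
    "filter_downsample",
    "blink_residualize",
    "preprocess_trace",
    "exclude_trials",
    "exclude_participants",
    "read_raw_gaze",
    "write_trace",
]

FS_INTERMEDIATE = 125.0
FS_OUT = 40.0
HANNING_S = 0.150
BLINK_MERGE_S = 0.100
BLINK_PAD_S = 0.200
BAND_HZ = (0.1, 4.0)
POST_BLINK_S = 1.6

MAX_INTERP_FRACTION = 0.35
MAX_GAP_S = 1.5
MAX_REMOVED_FRACTION = 0.50
MIN_TRIALS_PER_CONDITION = 13


@dataclass
class RawGaze:
    """Irregularly sampled eye-tracker records (timestamps in seconds)."""

    timestamps: np.ndarray
    pupil_area: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pupil_area = np.asarray(self.pupil_area, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.timestamps), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps) == len(self.pupil_area) == len(self.valid)):
            raise ValueError("raw gaze field lengths differ")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class PupilTrace:
    """Regularly sampled pupil signal plus interpolation bookkeeping."""

    fs: float
    samples: np.ndarray
    interp_mask: np.ndarray
    blink_offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.interp_mask = np.asarray(self.interp_mask, dtype=bool)
        self.blink_offsets = np.asarray(self.blink_offsets, dtype=float)
        if len(self.samples) != len(self.interp_mask):
            raise ValueError("interp_mask length mismatch")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


def _hanning_smooth(x: np.ndarray, fs: float, width_s: float = HANNING_S) -> np.ndarray:
    n = int(round(width_s * fs))
    n += 1 - n % 2  # odd length so the kernel is centered
    win = np.hanning(n + 2)[1:-1]
    win /= win.sum()
    half = n // 2
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, win, mode="valid")


def regularize(raw: RawGaze, fs: float = FS_INTERMEDIATE) -> PupilTrace:
    """Resample irregular records onto a uniform grid and smooth.

    Valid samples are linearly interpolated in time onto the ``fs`` grid, then
    smoothed with a 150-ms Hanning window (reflection at the edges).  Grid
    points farther than two nominal raw sampling intervals from any valid raw
    sample are flagged in ``interp_mask`` (they carry no data of their own).
    """
    t_valid = raw.timestamps[raw.valid]
    y_valid = raw.pupil_area[raw.valid]
    if len(t_valid) < 2:
        raise ValueError("need at least two valid samples")
    t0, t1 = raw.timestamps[0], raw.timestamps[-1]
    t_grid = t0 + np.arange(int(np.floor((t1 - t0) * fs)) + 1) / fs
    y = np.interp(t_grid, t_valid, y_valid)

    # distance to the nearest valid raw sample
    idx = np.searchsorted(t_valid, t_grid)
    idx_lo = np.clip(idx - 1, 0, len(t_valid) - 1)
    idx_hi = np.clip(idx, 0, len(t_valid) - 1)
    dist = np.minimum(
        np.abs(t_grid - t_valid[idx_lo]), np.abs(t_valid[idx_hi] - t_grid)
    )
    nominal_dt = float(np.median(np.diff(raw.timestamps)))
    mask = dist > 2.0 * nominal_dt

    y = _hanning_smooth(y, fs)
    return PupilTrace(fs=fs, samples=y, interp_mask=mask, t0=float(t_grid[0]))


def detect_blinks(
    trace: PupilTrace,
    z_thresh: float = 3.0,
    merge_s: float = BLINK_MERGE_S,
    pad_s: float = BLINK_PAD_S,
) -> list[tuple[int, int]]:
    """Artifact segments from rapid amplitude changes.

    Samples whose z-scored first difference exceeds ``z_thresh`` in magnitude
    seed segments; segments closer than ``merge_s`` are merged and each is
    extended ``pad_s`` beyond its offset (eye-tracker re-capture transient).
    Returns half-open sample-index intervals ``(start, stop)``.
    """
    d = np.diff(trace.samples)
    sd = d.std()
    if sd == 0:
        return []
    z = (d - d.mean()) / sd
    hot = np.abs(z) > z_thresh
    if not hot.any():
        return []
    # a hot difference d[i] implicates samples i and i+1
    flags = np.zeros(len(trace), dtype=bool)
    flags[:-1] |= hot
    flags[1:] |= hot

    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.astype(np.int8), [0]])))
    starts, stops = edges[::2], edges[1::2]

    merge_n = int(round(merge_s * trace.fs))
    pad_n = int(round(pad_s * trace.fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < merge_n:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    out: list[tuple[int, int]] = []
    for s, e in merged:
        e = min(e + pad_n, len(trace))
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interpolate_gaps(
    trace: PupilTrace, segments: Sequence[tuple[int, int]]
) -> PupilTrace:
    """Replace artifact segments by shape-preserving piecewise-cubic values.

    PCHIP through the surrounding clean samples guarantees no overshoot on
    monotone flanks.  Segments touching the trace edge are filled with the
    nearest clean value and flagged.
    """
    if not segments:
        return trace
    bad = np.zeros(len(trace), dtype=bool)
    for s, e in segments:
        if not (0 <= s < e <= len(trace)):
            raise ValueError("segment outside trace extent")
        bad[s:e] = True
    good = ~bad
    if good.sum() < 2:
        raise ValueError("not enough clean samples to interpolate")
    y = trace.samples.copy()
    t = np.arange(len(trace))
    first, last = t[good].min(), t[good].max()
    interior = bad & (t >= first) & (t <= last)
    edge = bad & ~interior
    if interior.any():
        y[interior] = PchipInterpolator(t[good], y[good])(t[interior])
    if edge.any():
        logger.info("edge artifact segment filled with nearest value")
        y[bad & (t < first)] = y[first]
        y[bad & (t > last)] = y[last]
    offsets = trace.t0 + np.array([e for _, e in segments]) / trace.fs
    return replace(
        trace,
        samples=y,
        interp_mask=trace.interp_mask | bad,
        blink_offsets=np.sort(np.concatenate([trace.blink_offsets, offsets])),
    )


def filter_downsample(trace: PupilTrace, fs_out: float = FS_OUT) -> PupilTrace:
    """Anti-aliased decimation to 40 Hz, then zero-phase 0.1-4 Hz band-pass.

    The band-pass is a 3rd-order Butterworth applied forward-backward
    (``sosfiltfilt``) so TRF latencies are not shifted.
    """
    if trace.fs != FS_INTERMEDIATE:
        raise ValueError("expected a 125 Hz trace")
    if len(trace) < 3 * int(trace.fs):
        raise ValueError("trace too short to filter")
    up, down = 8, 25  # 125 -> 40 Hz
    y = signal.resample_poly(trace.samples, up, down, padtype="line")
    t_new = trace.t0 + np.arange(len(y)) / fs_out
    mask = np.interp(t_new, trace.times, trace.interp_mask.astype(float)) > 0.5

    sos = signal.butter(3, BAND_HZ, btype="bandpass", fs=fs_out, output="sos")
    y = signal.sosfiltfilt(sos, y)
    return replace(trace, fs=fs_out, samples=y, interp_mask=mask)


def blink_residualize(
    trace: PupilTrace, blink_offsets: np.ndarray | None = None
) -> PupilTrace:
    """Regress out the stereotyped post-blink recovery from the trace.

    An impulse train at blink offsets is convolved with the *data-estimated*
    mean pupil course over the 1.6 s following offsets; the convolved
    regressor (plus intercept) is removed by least squares.
    """
    offsets = trace.blink_offsets if blink_offsets is None else np.asarray(
        blink_offsets, dtype=float
    )
    if len(offsets) == 0:
        return trace
    n_kernel = int(round(POST_BLINK_S * trace.fs))
    onsets_idx = np.round((offsets - trace.t0) * trace.fs).astype(int)
    onsets_idx = onsets_idx[(onsets_idx >= 0) & (onsets_idx < len(trace))]
    epochs = [
        trace.samples[i : i + n_kernel]
        for i in onsets_idx
        if i + n_kernel <= len(trace)
    ]
    if not epochs:
        return trace
    kernel = np.mean(epochs, axis=0)

    impulses = np.zeros(len(trace))
    impulses[onsets_idx] = 1.0
    reg = signal.fftconvolve(impulses, kernel)[: len(trace)]
    design = np.column_stack([reg, np.ones(len(trace))])
    coef, *_ = np.linalg.lstsq(design, trace.samples, rcond=None)
    return replace(trace, samples=trace.samples - design @ coef)


def preprocess_trace(raw: RawGaze, z_thresh: float = 3.0) -> PupilTrace:
    """Full chain: regularize, detect artifacts, interpolate, decimate,
    band-pass, blink-residualize."""
    trace = regularize(raw)
    segments = detect_blinks(trace, z_thresh=z_thresh)
    trace = interpolate_gaps(trace, segments)
    trace = filter_downsample(trace)
    return blink_residualize(trace)


def _max_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def exclude_trials(
    trials: Sequence[tuple[PupilTrace, dict]],
    max_interp_fraction: float = MAX_INTERP_FRACTION,
    max_gap_s: float = MAX_GAP_S,
) -> tuple[list[int], dict]:
    """Keep-indices and a report for the per-trial exclusion rules.

    A trial is dropped when its interpolated fraction reaches 35% or when any
    contiguous interpolated run lasts 1.5 s or longer.
    """
    kept, rows = [], []
    for i, (trace, meta) in enumerate(trials):
        frac = float(trace.interp_mask.mean())
        gap_s = _max_run(trace.interp_mask) / trace.fs
        drop = frac >= max_interp_fraction or gap_s >= max_gap_s
        if not drop:
            kept.append(i)
        rows.append(
            {
                "trial": i,
                "interp_fraction": frac,
                "max_gap_s": gap_s,
                "kept": bool(not drop),
                **meta,
            }
        )
    return kept, {"per_trial": rows, "n_kept": len(kept), "n_total": len(trials)}


def exclude_participants(
    sessions: dict[str, dict], mode: str = "trf"
) -> tuple[list[str], dict]:
    """Participant-level exclusions.

    Each value of ``sessions`` provides ``n_total``, ``n_kept`` and (for
    condition mode) ``kept_by_condition`` (condition -> count).  ``trf`` mode
    drops participants with more than 50% of trials removed; ``condition``
    mode drops participants with any condition below 13 remaining trials.
    """
    if mode not in ("trf", "condition"):
        raise ValueError(f"unknown mode {mode!r}")
    kept, rows = [], []
    for pid, info in sessions.items():
        if mode == "trf":
            removed = 1.0 - info["n_kept"] / info["n_total"]
            drop = removed > MAX_REMOVED_FRACTION
            rows.append(
                {"participant": pid, "removed_fraction": removed, "kept": bool(not drop)}
            )
        else:
            counts = info["kept_by_condition"]
            drop = any(c < MIN_TRIALS_PER_CONDITION for c in counts.values())
            rows.append(
                {
                    "participant": pid,
                    "min_condition_count": min(counts.values()),
                    "kept": bool(not drop),
                }
            )
        if not drop:
            kept.append(pid)
    return kept, {"mode": mode, "per_participant": rows}


def read_raw_gaze(path: str | Path) -> RawGaze:
    df = pd.read_csv(path)
    return RawGaze(
        df["timestamp_s"].to_numpy(),
        df["pupil_area"].to_numpy(),
        df["valid"].to_numpy(dtype=bool) if "valid" in df else None,
    )


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t": trace.times,
            "pupil": trace.samples,
            "interp": trace.interp_mask.astype(int),
        }
    ).to_csv(path, index=False)
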
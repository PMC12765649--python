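"""Stochastic tone-sequence generation.

Trials are 60-tone sequences presented at 4 Hz (200 ms tones, 50 ms gaps).
Tones are drawn from a two-component Gaussian mixture over log-frequency
(octaves re 500 Hz) and quantized to a 1/12-octave grid.  Each trial has a
hidden boundary after 20 +/- 5 tones at which the generating distribution may
change, producing five conditions:

========  ==========================================================
LE-LE     low entropy throughout (narrow sigma, one dominant source)
LE-HE     low entropy, then high entropy (broad sigma, 50/50 sources)
LE-dLE    low entropy, then a *distinct* low-entropy context in which
          the dominant source is swapped
HE-LE     high entropy, then low entropy
HE-HE     high entropy throughout
========  ==========================================================

All frequencies are handled in octaves relative to 500 Hz; conversion to Hz
happens only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "DistributionSpec",
    "ToneSequence",
    "Session",
    "SessionConfig",
    "draw_condition_spec",
    "quantize_freq",
    "generate_trial",
    "generate_session",
    "write_session",
    "read_session_events",
    "read_session",
]

#: presentation rate and trial geometry
TONE_RATE_HZ = 4.0
TONE_SOA_S = 1.0 / TONE_RATE_HZ
TONE_DURATION_S = 0.2
N_TONES = 60
BOUNDARY_RANGE = (15, 25)  # inclusive, tone index of first post-boundary tone

#: frequency geometry, octaves re 500 Hz
REF_HZ = 500.0
CENTER_LO_OCT = 0.0                      # 500 Hz
CENTER_HI_OCT = float(np.log2(3000.0 / REF_HZ))   # 3 kHz
MIN_SEPARATION_OCT = 1.3
BAND_LO_OCT = -1.0                       # 250 Hz, redraw limit for samples
BAND_HI_OCT = float(np.log2(6000.0 / REF_HZ))     # 6 kHz
GRID_STEP_OCT = 1.0 / 12.0

#: condition-level parameter jitter (level -> (sigma_mid, sigma_jit, p_mid, p_jit))
LEVEL_PARAMS = {
    "LE": (0.20, 0.15, 0.90, 0.05),
    "HE": (1.85, 0.15, 0.50, 0.05),
}

CONDITIONS = ("LE-LE", "LE-HE", "LE-dLE", "HE-LE", "HE-HE")


@dataclass(frozen=True)
class DistributionSpec:
    """Two-source Gaussian mixture over octaves; one source may dominate."""

    center_lo: float
    center_hi: float
    sigma: float
    p_primary: float
    primary: str  # "lo" | "hi"

    def __post_init__(self) -> None:
        if self.center_hi - self.center_lo < MIN_SEPARATION_OCT - 1e-12:
            raise ValueError("centers closer than minimum separation")
        for c in (self.center_lo, self.center_hi):
            if not (CENTER_LO_OCT - 1e-12 <= c <= CENTER_HI_OCT + 1e-12):
                raise ValueError("center outside the 500 Hz - 3 kHz range")
        if not 0.0 <= self.p_primary <= 1.0:
            raise ValueError("p_primary must be a probability")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.primary not in ("lo", "hi"):
            raise ValueError("primary must be 'lo' or 'hi'")

    @property
    def primary_center(self) -> float:
        return self.center_lo if self.primary == "lo" else self.center_hi

    @property
    def secondary_center(self) -> float:
        return self.center_hi if self.primary == "lo" else self.center_lo

    def swap_primary(self) -> "DistributionSpec":
        return replace(self, primary="hi" if self.primary == "lo" else "lo")


@dataclass
class ToneSequence:
    """One trial: quantized tone frequencies, onsets, and boundary metadata."""

    freqs: np.ndarray          # octaves re 500 Hz, on the 1/12-oct grid
    onsets: np.ndarray         # seconds from trial start
    condition: str
    boundary_idx: int
    pre_spec: DistributionSpec
    post_spec: DistributionSpec

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.freqs) != len(self.onsets):
            raise ValueError("freqs and onsets length mismatch")
        if not BOUNDARY_RANGE[0] <= self.boundary_idx <= BOUNDARY_RANGE[1]:
            raise ValueError("boundary index out of range")

    def __len__(self) -> int:
        return len(self.freqs)

    @property
    def freqs_hz(self) -> np.ndarray:
        return REF_HZ * 2.0 ** self.freqs

    @property
    def boundary_time_s(self) -> float:
        return float(self.onsets[self.boundary_idx])

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "tone_index": np.arange(n),
                "onset_s": self.onsets,
                "freq_oct": self.freqs,
                "freq_hz": self.freqs_hz,
                "is_post_boundary": np.arange(n) >= self.boundary_idx,
                "condition": self.condition,
            }
        )


@dataclass
class SessionConfig:
    """Session layout; defaults give 9 blocks x 16 trials = 144 trials."""

    n_blocks: int = 9
    trials_per_block: int = 16
    iti_s: float = 6.0
    sigma_jitter: float = 1.0   # scale on the +/- jitter amplitudes (0 = none)
    conditions: Sequence[str] = CONDITIONS
    proportions: Sequence[float] | None = None  # None = near-equal round-robin

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class Session:
    trials: list[ToneSequence]
    block_index: np.ndarray
    iti_s: float
    seed: int
    centers: tuple[float, float]

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, trial in enumerate(self.trials):
            df = trial.to_frame()
            df.insert(0, "trial", i)
            df.insert(1, "block", int(self.block_index[i]))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def quantize_freq(f: float | np.ndarray) -> float | np.ndarray:
    """Round an octave value to the nearest 1/12 octave (ties to even)."""
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite frequency")
    out = np.round(np.asarray(f, dtype=float) * 12.0) / 12.0
    return float(out) if np.isscalar(f) else out


def draw_condition_spec(
    level: str,
    centers: tuple[float, float],
    rng: np.random.Generator,
    sigma_jitter: float = 1.0,
) -> DistributionSpec:
    """Draw jittered distribution parameters for an entropy level.

    LE: sigma = 0.2 +/- 0.15 oct, p(primary) = 0.90 +/- 0.05.
    HE: sigma = 1.85 +/- 0.15 oct, p(primary) = 0.50 +/- 0.05.
    ``sigma_jitter`` scales both jitter amplitudes (0 disables jitter).
    """
    if level not in LEVEL_PARAMS:
        raise ValueError(f"unknown entropy level {level!r}")
    s_mid, s_jit, p_mid, p_jit = LEVEL_PARAMS[level]
    sigma = s_mid + sigma_jitter * s_jit * rng.uniform(-1.0, 1.0)
    p_primary = p_mid + sigma_jitter * p_jit * rng.uniform(-1.0, 1.0)
    primary = "lo" if rng.uniform() < 0.5 else "hi"
    lo, hi = sorted(centers)
    return DistributionSpec(lo, hi, sigma, p_primary, primary)


def _sample_tone(spec: DistributionSpec, rng: np.random.Generator) -> float:
    center = spec.primary_center if rng.uniform() < spec.p_primary else spec.secondary_center
    while True:
        f = rng.normal(center, spec.sigma)
        if BAND_LO_OCT <= f <= BAND_HI_OCT:
            return float(quantize_freq(f))


def _condition_specs(
    condition: str,
    centers: tuple[float, float],
    rng: np.random.Generator,
    sigma_jitter: float,
) -> tuple[DistributionSpec, DistributionSpec]:
    pre_level, post_level = condition.split("-")
    pre = draw_condition_spec(pre_level, centers, rng, sigma_jitter)
    if condition in ("LE-LE", "HE-HE"):
        post = pre
    elif condition == "LE-dLE":
        post = pre.swap_primary()
    else:
        post = draw_condition_spec(post_level, centers, rng, sigma_jitter)
    return pre, post


def generate_trial(
    condition: str,
    rng: np.random.Generator,
    centers: tuple[float, float] = (CENTER_LO_OCT, CENTER_HI_OCT),
    sigma_jitter: float = 1.0,
) -> ToneSequence:
    """Generate one 60-tone trial with a jittered boundary for ``condition``."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    pre, post = _condition_specs(condition, centers, rng, sigma_jitter)
    boundary = int(rng.integers(BOUNDARY_RANGE[0], BOUNDARY_RANGE[1] + 1))
    freqs = np.array(
        [_sample_tone(pre if i < boundary else post, rng) for i in range(N_TONES)]
    )
    onsets = np.arange(N_TONES) * TONE_SOA_S
    return ToneSequence(freqs, onsets, condition, boundary, pre, post)


def _condition_schedule(cfg: SessionConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_trials
    conds = list(cfg.conditions)
    if cfg.proportions is None:
        # round-robin: counts differ by at most one across conditions
        schedule = [conds[i % len(conds)] for i in range(n)]
    else:
        props = np.asarray(cfg.proportions, dtype=float)
        if len(props) != len(conds):
            raise ValueError("one proportion per condition required")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("condition proportions must sum to 1")
        counts = np.floor(props * n).astype(int)
        order = np.argsort(props * n - counts)[::-1]
        for i in order[: n - counts.sum()]:
            counts[i] += 1
        schedule = [c for c, k in zip(conds, counts) for _ in range(int(k))]
    rng.shuffle(schedule)
    return schedule


def generate_session(
    config: SessionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Session:
    """Generate a full session (default: 144 trials over 5 conditions).

    Mixture center frequencies are drawn once per session, uniform within
    500 Hz-3 kHz subject to the >= 1.3 octave separation, and reused by every
    trial so that dLE primary swaps refer to the same pair of sources.
    """
    config = config or SessionConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(seed)
    else:
        seed = -1  # external generator; seed not recorded

    lo = rng.uniform(CENTER_LO_OCT, CENTER_HI_OCT - MIN_SEPARATION_OCT)
    hi = rng.uniform(lo + MIN_SEPARATION_OCT, CENTER_HI_OCT)
    centers = (float(lo), float(hi))

    schedule = _condition_schedule(config, rng)
    trials = [
        generate_trial(c, rng, centers, config.sigma_jitter) for c in schedule
    ]
    block_index = np.repeat(np.arange(config.n_blocks), config.trials_per_block)[
        : len(trials)
    ]
    return Session(trials, block_index, config.iti_s, int(seed), centers)


def write_session(session: Session, out_dir: str | Path) -> None:
    """Write a session as ``events.csv`` plus a JSON manifest of specs/seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session.to_frame().to_csv(out_dir / "events.csv", index=False)
    manifest = {
        "seed": session.seed,
        "iti_s": session.iti_s,
        "centers_oct": list(session.centers),
        "n_trials": len(session),
        "trials": [
            {
                "condition": t.condition,
                "boundary_idx": t.boundary_idx,
                "pre_spec": vars(t.pre_spec),
                "post_spec": vars(t.post_spec),
            }
            for t in session.trials
        ],
    }
    (out_dir / "session.json").write_text(json.dumps(manifest, indent=1))


def read_session_events(path: str | Path) -> pd.DataFrame:
    """Read an ``events.csv`` event table written by :func:`write_session`."""
    return pd.read_csv(Path(path) if str(path).endswith(".csv") else Path(path) / "events.csv")


def read_session(dir_path: str | Path) -> Session:
    """Reconstruct a :class:`Session` from ``events.csv`` + ``session.json``."""
    dir_path = Path(dir_path)
    events = pd.read_csv(dir_path / "events.csv")
    manifest = json.loads((dir_path / "session.json").read_text())
    trials = []
    for i, meta in enumerate(manifest["trials"]):
        df = events[events["trial"] == i]
        trials.append(
            ToneSequence(
                freqs=df["freq_oct"].to_numpy(),
                onsets=df["onset_s"].to_numpy(),
                condition=meta["condition"],
                boundary_idx=int(meta["boundary_idx"]),
                pre_spec=DistributionSpec(**meta["pre_spec"]),
                post_spec=DistributionSpec(**meta["post_spec"]),
            )
        )
    block_index = events.groupby("trial")["block"].first().to_numpy()
    return Session(
        trials,
        block_index,
        float(manifest["iti_s"]),
        int(manifest["seed"]),
        tuple(manifest["centers_oct"]),
    )
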
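"""Stage orchestration: configuration, provenance, and file contracts.

``run_pipeline`` executes the analysis stages in dependency order on a
directory tree, writing a manifest (config hash, derived seeds, output
checksums) that makes re-runs idempotent: a stage is skipped when the
manifest records it as complete under the same configuration, unless
``force`` is set.

All tabular interchange is plain CSV (comma, header row, UTF-8, '.'
decimal); reports are JSON.  Every stochastic stage derives its seed
deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import boundary, groupstats, preprocess, stimgen, synthpupil, trf
from .observers import ObserverConfig, regressor_frame, session_traces
from .synthpupil import SimConfig

logger = logging.getLogger("pupilpredict.pipeline")

STAGES = (
    "stimuli",
    "observers",
    "pupil",
    "preprocess",
    "trf",
    "boundary",
    "groupstats",
)

TRANSITION_CONTROL = {"LE-HE": "LE-LE", "LE-dLE": "LE-LE", "HE-LE": "HE-HE"}


@dataclass
class PipelineConfig:
    """One block per module plus a global seed and output root."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    stimgen: dict = field(default_factory=dict)      # SessionConfig fields
    observers: dict = field(default_factory=dict)    # ObserverConfig fields
    synthpupil: dict = field(default_factory=dict)   # SimConfig fields
    preprocess: dict = field(default_factory=dict)   # z_thresh
    trf: dict = field(default_factory=dict)          # target_folds, tolerance
    boundary: dict = field(default_factory=dict)     # baseline_s
    groupstats: dict = field(default_factory=dict)   # n_perm, n_boot, alpha

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, root: Path, cfg: PipelineConfig):
        self.path = root / "manifest.json"
        self.cfg_digest = cfg.digest()
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_digest") != self.cfg_digest:
                self.data = {"config_digest": self.cfg_digest, "stages": {}}
        else:
            self.data = {"config_digest": self.cfg_digest, "stages": {}}

    def done(self, stage: str, outputs: Sequence[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        return all(
            Path(p).exists() and _checksum(Path(p)) == c
            for p, c in rec["outputs"].items()
        )

    def record(self, stage: str, outputs: Sequence[Path], seed: int) -> None:
        self.data["stages"][stage] = {
            "seed": seed,
            "outputs": {str(p): _checksum(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_stimuli(cfg: PipelineConfig, root: Path) -> list[Path]:
    sess_cfg = stimgen.SessionConfig(**cfg.stimgen)
    session = stimgen.generate_session(sess_cfg, cfg.stage_seed("stimuli"))
    stimgen.write_session(session, root / "stimuli")
    return [root / "stimuli" / "events.csv", root / "stimuli" / "session.json"]


def _load_session(root: Path) -> stimgen.Session:
    return stimgen.read_session(root / "stimuli")


def _stage_observers(cfg: PipelineConfig, root: Path) -> list[Path]:
    session = _load_session(root)
    obs_cfg = ObserverConfig(**cfg.observers)
    out = root / "observers"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in ("drex", "ideal"):
        traces = session_traces(session, obs_cfg, model=model)
        frame = regressor_frame(session, traces, model)
        p = out / f"regressors_{model}.csv"
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths


def _stage_pupil(cfg: PipelineConfig, root: Path) -> list[Path]:
    session = _load_session(root)
    obs_cfg = ObserverConfig(**cfg.observers)
    sim_cfg = SimConfig(**cfg.synthpupil)
    traces = session_traces(session, obs_cfg, model="drex")
    kernels = synthpupil.default_kernels()
    rng = np.random.default_rng(cfg.stage_seed("pupil"))
    out = root / "pupil"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(sim_cfg.n_participants):
        pk = synthpupil._jittered_kernels(kernels, sim_cfg.kernel_jitter, rng)
        raws = synthpupil.simulate_participant(session, traces, pk, sim_cfg, rng)
        frames = []
        for i, raw in enumerate(raws):
            frames.append(
                pd.DataFrame(
                    {
                        "trial": i,
                        "timestamp_s": raw.timestamps,
                        "pupil_area": raw.pupil_area,
                        "valid": raw.valid.astype(int),
                    }
                )
            )
        path = out / f"raw_p{p:02d}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        paths.append(path)
    return paths


def _stage_preprocess(cfg: PipelineConfig, root: Path) -> list[Path]:
    z = cfg.preprocess.get("z_thresh", 3.0)
    out = root / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    session = _load_session(root)
    conditions = [t.condition for t in session.trials]
    paths = []
    exclusion = {}
    for raw_path in sorted((root / "pupil").glob("raw_p*.csv")):
        pid = raw_path.stem.replace("raw_", "")
        df = pd.read_csv(raw_path)
        frames = []
        trials_for_exclusion = []
        for t_idx, g in df.groupby("trial"):
            raw = preprocess.RawGaze(
                g["timestamp_s"].to_numpy(),
                g["pupil_area"].to_numpy(),
                g["valid"].to_numpy(dtype=bool),
            )
            trace = synthpupil.crop_trace(preprocess.preprocess_trace(raw, z))
            trials_for_exclusion.append((trace, {"condition": conditions[t_idx]}))
            f = pd.DataFrame(
                {
                    "trial": t_idx,
                    "t": trace.times,
                    "pupil": trace.samples,
                    "interp": trace.interp_mask.astype(int),
                }
            )
            frames.append(f)
        kept, report = preprocess.exclude_trials(trials_for_exclusion)
        exclusion[pid] = {
            "n_total": report["n_total"],
            "n_kept": report["n_kept"],
            "kept_trials": kept,
            "kept_by_condition": {
                c: sum(1 for i in kept if conditions[i] == c)
                for c in set(conditions)
            },
        }
        path = out / f"traces_{pid}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        paths.append(path)
    report_path = out / "exclusions.json"
    report_path.write_text(json.dumps(exclusion, indent=1, sort_keys=True))
    paths.append(report_path)
    return paths


def _participant_data(cfg: PipelineConfig, root: Path, pid: str):
    session = _load_session(root)
    reg = pd.read_csv(root / "observers" / "regressors_drex.csv")
    traces = pd.read_csv(root / "preprocess" / f"traces_{pid}.csv")
    exclusion = json.loads((root / "preprocess" / "exclusions.json").read_text())
    kept = exclusion[pid]["kept_trials"]

    bounds = {
        name: (float(reg[name].min()), float(reg[name].max()))
        for name in ("surprisal", "precision")
    }
    events, y_trials, boundary_idx, conds = [], [], [], []
    n_samples = int(
        round((synthpupil.TRIAL_EPOCH_S[1] - synthpupil.TRIAL_EPOCH_S[0]) * trf.FS)
    )
    for t_idx in kept:
        r = reg[reg["trial"] == t_idx]
        onsets = np.round(
            (r["onset_s"].to_numpy() - synthpupil.TRIAL_EPOCH_S[0]) * trf.FS
        ).astype(int)
        values = {
            name: trf.normalize_regressor(r[name].to_numpy(), *bounds[name])
            for name in ("surprisal", "precision")
        }
        events.append(trf.EventSeries(onsets, values, n_samples))
        y = traces[traces["trial"] == t_idx]["pupil"].to_numpy()
        y_trials.append(trf.zscore_trial(y))
        tr = session.trials[t_idx]
        boundary_idx.append(
            int(round((tr.boundary_time_s - synthpupil.TRIAL_EPOCH_S[0]) * trf.FS))
        )
        conds.append(tr.condition)
    return events, y_trials, boundary_idx, conds


def _stage_trf(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "trf"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.stage_seed("trf"))
    paths = []
    reports = {}
    for tr_path in sorted((root / "preprocess").glob("traces_p*.csv")):
        pid = tr_path.stem.replace("traces_", "")
        events, y_trials, _, _ = _participant_data(cfg, root, pid)
        folds, mean_trf, report = trf.crossval_trf(
            events,
            y_trials,
            rng=rng,
            target_folds=cfg.trf.get("target_folds", 8),
            tolerance=cfg.trf.get("tolerance", 2),
        )
        rows = []
        for est, fold_label in [(mean_trf, "mean")] + [
            (e, str(e.fold_id)) for e in folds
        ]:
            for name, coefs in est.coefficients.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "regressor": name,
                            "lag_s": est.lags,
                            "coefficient": coefs,
                            "fold": fold_label,
                        }
                    )
                )
        path = out / f"trf_{pid}.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        paths.append(path)
        reports[pid] = report
    rep = out / "fit_report.json"
    rep.write_text(json.dumps(reports, indent=1, sort_keys=True))
    paths.append(rep)
    return paths


def _stage_boundary(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "boundary"
    out.mkdir(parents=True, exist_ok=True)
    baseline = tuple(cfg.boundary.get("baseline_s", boundary.DEFAULT_BASELINE_S))
    frames = []
    for tr_path in sorted((root / "trf").glob("trf_p*.csv")):
        pid = tr_path.stem.replace("trf_", "")
        events, y_trials, b_idx, conds = _participant_data(cfg, root, pid)
        tdf = pd.read_csv(tr_path)
        tdf = tdf[tdf["fold"] == "mean"]
        coefs = {
            name: g.sort_values("lag_s")["coefficient"].to_numpy()
            for name, g in tdf.groupby("regressor")
        }
        fit = trf.TRFEstimate(trf.lag_grid(), coefs)
        resid = boundary.residualize_surprisal(y_trials, events, fit)
        erps = []
        for cond in stimgen.CONDITIONS:
            trials = [
                (resid[i], b_idx[i]) for i in range(len(conds)) if conds[i] == cond
            ]
            if trials:
                erps.append(
                    boundary.boundary_erp(trials, cond, baseline_s=baseline)
                )
        frames.append(boundary.erp_frame(erps, pid))
    path = out / "erp.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_groupstats(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "groupstats"
    out.mkdir(parents=True, exist_ok=True)
    n_perm = cfg.groupstats.get("n_perm", 10_000)
    n_boot = cfg.groupstats.get("n_boot", 10_000)
    alpha = cfg.groupstats.get("alpha", 0.05)
    seed = cfg.stage_seed("groupstats")
    results = {}

    # TRF one-sample tests vs the pre-onset baseline, Bonferroni over 2 TRFs
    trf_files = sorted((root / "trf").glob("trf_p*.csv"))
    curves = {"surprisal": [], "precision": []}
    for f in trf_files:
        df = pd.read_csv(f)
        df = df[df["fold"] == "mean"]
        for name, g in df.groupby("regressor"):
            curves[name].append(g.sort_values("lag_s")["coefficient"].to_numpy())
    lags = trf.lag_grid()
    band_rows = []
    for k, name in enumerate(curves):
        mat = np.vstack(curves[name])
        res = groupstats.cluster_permutation(
            mat,
            times=lags,
            baseline=(-0.5, 0.0),
            n_perm=n_perm,
            alpha=alpha,
            rng=seed + k,
        )
        lo, hi = groupstats.bootstrap_ci(mat, n_boot=n_boot, rng=seed + 10 + k)
        band_rows.append(
            pd.DataFrame(
                {"regressor": name, "lag_s": lags, "mean": mat.mean(0), "lo": lo, "hi": hi}
            )
        )
        results[f"trf_{name}"] = {
            "clusters": [
                {
                    "t_start": c.t_start,
                    "t_end": c.t_end,
                    "p_corrected": groupstats.bonferroni(c.p_corrected, 2),
                }
                for c in res.clusters
            ],
            "n_permutations": n_perm,
        }

    # boundary contrasts vs controls, Bonferroni over 3 comparisons
    erp = pd.read_csv(root / "boundary" / "erp.csv")
    for trans, control in TRANSITION_CONTROL.items():
        diffs, times = [], None
        for pid, g in erp.groupby("participant"):
            a = g[g["condition"] == trans].sort_values("t_rel_boundary")
            b = g[g["condition"] == control].sort_values("t_rel_boundary")
            if len(a) == 0 or len(b) == 0:
                continue
            times = a["t_rel_boundary"].to_numpy()
            diffs.append(a["value"].to_numpy() - b["value"].to_numpy())
        if len(diffs) < 5:
            continue
        mat = np.vstack(diffs)
        sel = (times >= 0) & (times <= 6.0)
        res = groupstats.cluster_permutation(
            mat[:, sel], times=times[sel], n_perm=n_perm, alpha=alpha, rng=seed + 20
        )
        clusters = []
        for c in res.clusters:
            win = (times[sel] >= c.t_start) & (times[sel] <= c.t_end)
            d = groupstats.cohens_d(mat[:, sel][:, win])
            clusters.append(
                {
                    "t_start": c.t_start,
                    "t_end": c.t_end,
                    "p_corrected": groupstats.bonferroni(c.p_corrected, 3),
                    "cohens_d": d,
                }
            )
        results[f"boundary_{trans}_vs_{control}"] = {
            "clusters": clusters,
            "n_permutations": n_perm,
        }

    path = out / "results.json"
    path.write_text(json.dumps(results, indent=1, sort_keys=True))
    bands = out / "bands.csv"
    pd.concat(band_rows, ignore_index=True).to_csv(bands, index=False)
    return [path, bands]


_STAGE_FN = {
    "stimuli": _stage_stimuli,
    "observers": _stage_observers,
    "pupil": _stage_pupil,
    "preprocess": _stage_preprocess,
    "trf": _stage_trf,
    "boundary": _stage_boundary,
    "groupstats": _stage_groupstats,
}

_DEPS = {
    "stimuli": (),
    "observers": ("stimuli",),
    "pupil": ("stimuli", "observers"),
    "preprocess": ("pupil",),
    "trf": ("observers", "preprocess"),
    "boundary": ("trf",),
    "groupstats": ("trf", "boundary"),
}


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the requested stages in order; returns the manifest dict.

    Raises if a requested stage's upstream outputs are missing, naming the
    missing stage.  Completed stages with unchanged config and intact outputs
    are skipped unless ``force``.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(root, config)

    for stage in stages:
        for dep in _DEPS[stage]:
            if dep not in stages and not manifest.done(dep, []):
                raise RuntimeError(
                    f"stage {stage!r} requires {dep!r}, which has not run"
                )
        if not force and manifest.done(stage, []):
            logger.info("[%s] up to date, skipped", stage)
            continue
        logger.info("[%s] running", stage)
        outputs = _STAGE_FN[stage](config, root)
        manifest.record(stage, outputs, config.stage_seed(stage))
    return manifest.data
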
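"""End-to-end orchestration: simulate or ingest a dataset, run REFRAME against
a reference marker set, and emit pairwise RMSE tables, correction transforms,
mean +/- SD waveforms and figures.

The per-knee fit concatenates all of a knee's cycle-normalized trials and
finds one correction pair per (marker set, knee); per-trial fitting is
available through ``fit_per_trial``.  All waveforms — raw and reframed — are
extracted from rotation series resampled to the normalized cycle grid by
spherical interpolation, so the two stages are exactly comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from . import io as rgio
from .dataset import MarkerSetDataset, PoseTrial
from .metrics import CHANNELS, ComparisonTable, pairwise_table
from .reframe import ReframeConfig, ReframeResult, apply_frame_corrections, optimize
from .rotations import N_NORM_DEFAULT, joint_rotation, _extract_cardan_rad
from .synthetic import SyntheticConfig, build_study

__all__ = ["RunManifest", "PipelineResult", "run_pipeline", "plot_mean_sd",
           "marker_set_spread", "normalized_joint_rotations"]

log = logging.getLogger("reframe_gait")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: input source, configs, seed.

    ``synthetic`` and ``dataset_path`` are mutually exclusive input sources.
    A completed run's manifest plus its inputs fully determine its numeric
    outputs.
    """

    reframe: ReframeConfig = field(default_factory=ReframeConfig)
    synthetic: Optional[SyntheticConfig] = None
    dataset_path: Optional[str] = None
    out_dir: Optional[str] = None  # no files written when unset
    seed: int = 0
    n_norm: int = N_NORM_DEFAULT
    fit_per_trial: bool = False
    make_plots: bool = True
    version: str = "0.1.0"

    def __post_init__(self):
        if (self.synthetic is None) == (self.dataset_path is None):
            raise ValueError("exactly one of synthetic / dataset_path must be set")
        if self.synthetic is not None and self.synthetic.seed != self.seed:
            self.synthetic = replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "reframe": dataclasses.asdict(self.reframe),
            "dataset_path": self.dataset_path,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_norm": self.n_norm,
            "fit_per_trial": self.fit_per_trial,
            "make_plots": self.make_plots,
            "version": self.version,
        }
        if self.synthetic is not None:
            d["synthetic"] = rgio._synthetic_to_dict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            d["synthetic"] = rgio.load_synthetic_config(syn)
        d["reframe"] = ReframeConfig(**d["reframe"])
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    dataset: MarkerSetDataset
    fits: Dict[Tuple[str, str, str], ReframeResult]  # (marker_set, subject, knee)
    raw_table: Optional[ComparisonTable]
    reframed_table: Optional[ComparisonTable]
    waveforms: pd.DataFrame
    raw_angles: Dict[Tuple[str, str, int], np.ndarray]
    reframed_angles: Dict[Tuple[str, str, int], np.ndarray]
    non_converged: List[Tuple[str, str, str]]
    out_dir: Optional[Path] = None


def normalized_joint_rotations(trial: PoseTrial, n_norm: int = N_NORM_DEFAULT) -> np.ndarray:
    """Joint rotations resampled to ``n_norm`` points per cycle by Slerp.

    Returns an ``(n_cycles * n_norm, 3, 3)`` stack; spherical interpolation of
    the joint rotation commutes with constant frame corrections, keeping raw
    and reframed waveforms on exactly the same footing.
    """
    J = joint_rotation(trial.femur, trial.tibia)
    slerp = Slerp(np.arange(trial.n_samples, dtype=float), Rotation.from_matrix(J))
    chunks = []
    events = trial.events
    for e0, e1 in zip(events[:-1], events[1:]):
        grid = np.linspace(float(e0), float(e1), n_norm)
        chunks.append(slerp(grid).as_matrix())
    return np.concatenate(chunks, axis=0)


def _angles_deg(T: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(_extract_cardan_rad(T), axis=0))


def _mean_sd_waveforms(angles: Dict[Tuple[str, str, int], np.ndarray],
                       stage: str, n_norm: int) -> pd.DataFrame:
    """Mean +/- SD per marker set across all knees and trials, display sign."""
    rows = []
    pct = np.linspace(0.0, 100.0, n_norm)
    sets = sorted({k[0] for k in angles})
    for ms in sets:
        stack = np.stack([w for (s, _, _), w in sorted(angles.items()) if s == ms])
        disp = stack.copy()
        disp[:, :, 0] *= -1.0  # flexion shown positive
        mean = disp.mean(axis=0)
        sd = disp.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
        for c, channel in enumerate(CHANNELS):
            for i in range(n_norm):
                rows.append({"marker_set": ms, "stage": stage, "pct": pct[i],
                             "channel": channel, "mean_deg": mean[i, c],
                             "sd_deg": sd[i, c]})
    return pd.DataFrame(rows)


def marker_set_spread(waveforms: pd.DataFrame, channel: str, stage: str,
                      pct_lo: float = 60.0, pct_hi: float = 90.0) -> float:
    """Largest across-marker-set divergence of the mean curves in a cycle
    window (default the swing phase), in degrees."""
    sub = waveforms[(waveforms.channel == channel) & (waveforms.stage == stage)
                    & (waveforms.pct >= pct_lo) & (waveforms.pct <= pct_hi)]
    piv = sub.pivot_table(index="pct", columns="marker_set", values="mean_deg")
    return float((piv.max(axis=1) - piv.min(axis=1)).max())


def _load_dataset(manifest: RunManifest) -> MarkerSetDataset:
    if manifest.synthetic is not None:
        log.info("building synthetic study (seed=%d)", manifest.seed)
        return build_study(manifest.synthetic)
    log.info("reading dataset from %s", manifest.dataset_path)
    ds = rgio.read_dataset(manifest.dataset_path)
    for key, trial in list(ds.trials.items()):
        if trial.side == "left" and not trial.mirrored:
            ds.trials[key] = trial.mirrored_copy()
    return ds


def run_pipeline(manifest: RunManifest,
                 dataset: Optional[MarkerSetDataset] = None) -> PipelineResult:
    """Execute the full analysis and (optionally) write the output bundle.

    Per marker set and knee, one constant correction pair is fitted on the
    concatenated normalized trials, using the reference marker set's raw
    flexion of the same knee as the flexion target (the reference set is
    optimized against its own raw flexion).
    """
    out_dir = Path(manifest.out_dir) if manifest.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setLevel(logging.INFO)
        log.addHandler(handler)
    try:
        return _run(manifest, dataset, out_dir)
    finally:
        if out_dir is not None:
            log.removeHandler(handler)
            handler.close()


def _run(manifest: RunManifest, dataset: Optional[MarkerSetDataset],
         out_dir: Optional[Path]) -> PipelineResult:
    ds = dataset if dataset is not None else _load_dataset(manifest)
    cfg = manifest.reframe
    n_norm = manifest.n_norm
    sets = ds.marker_sets
    reference = cfg.reference_label
    if reference not in sets:
        if len(sets) == 1:
            reference = sets[0]
            log.warning("reference %r absent; single marker set %r optimized "
                        "against its own flexion", cfg.reference_label, reference)
        else:
            raise ValueError(f"reference marker set {cfg.reference_label!r} "
                             f"not in dataset sets {sets}")

    # 1. normalized joint rotations and raw waveforms per trial
    T_norm: Dict[Tuple[str, str, str, int], np.ndarray] = {}
    raw_angles: Dict[Tuple[str, str, int], np.ndarray] = {}
    for trial in ds:
        T = normalized_joint_rotations(trial, n_norm)
        T_norm[(trial.marker_set, trial.subject, trial.knee, trial.trial)] = T
        raw_angles[(trial.marker_set, trial.knee, trial.trial)] = _angles_deg(T)

    # 2. REFRAME fits
    fits: Dict[Tuple[str, str, str], ReframeResult] = {}
    reframed_angles: Dict[Tuple[str, str, int], np.ndarray] = {}
    non_converged: List[Tuple[str, str, str]] = []
    trial_ids = ds.trial_ids()
    for (subject, knee) in ds.knees():
        ref_flex = np.concatenate([
            _angles_deg(T_norm[(reference, subject, knee, t)])[:, 0] for t in trial_ids])
        for ms in sets:
            if manifest.fit_per_trial:
                for t in trial_ids:
                    T = T_norm[(ms, subject, knee, t)]
                    ref_t = _angles_deg(T_norm[(reference, subject, knee, t)])[:, 0]
                    res = optimize(T, ref_t, cfg)
                    fits[(ms, subject, f"{knee}#t{t}")] = res
                    reframed_angles[(ms, knee, t)] = res.optimized.angles_deg
                continue
            T_cat = np.concatenate([T_norm[(ms, subject, knee, t)] for t in trial_ids])
            res = optimize(T_cat, ref_flex, cfg)
            fits[(ms, subject, knee)] = res
            if not res.converged:
                non_converged.append((ms, subject, knee))
                log.warning("non-converged fit: set=%s knee=%s", ms, knee)
            log.info("fit set=%-10s knee=%s cost %0.3f -> %0.4f (evals=%d)",
                     ms, knee, res.cost_initial, res.cost_final, res.n_evaluations)
            for t in trial_ids:
                T = T_norm[(ms, subject, knee, t)]
                corrected = apply_frame_corrections(T, res.R_fem_corr, res.R_tib_corr)
                reframed_angles[(ms, knee, t)] = corrected.angles_deg

    # 3. tables and waveforms
    raw_table = reframed_table = None
    if len(sets) >= 2:
        raw_table = pairwise_table(raw_angles, "raw")
        reframed_table = pairwise_table(reframed_angles, "reframed")
    else:
        log.warning("single marker set: pairwise table empty")
    # waveform statistics use the first cycle of each trial
    waveforms = pd.concat([
        _mean_sd_waveforms({k: v[:n_norm] for k, v in raw_angles.items()},
                           "raw", n_norm),
        _mean_sd_waveforms({k: v[:n_norm] for k, v in reframed_angles.items()},
                           "reframed", n_norm),
    ], ignore_index=True)

    result = PipelineResult(ds, fits, raw_table, reframed_table, waveforms,
                            raw_angles, reframed_angles, non_converged, out_dir)
    if out_dir is not None:
        _write_outputs(manifest, result, out_dir)
    return result


def _write_outputs(manifest: RunManifest, result: PipelineResult, out_dir: Path) -> None:
    (out_dir / "tables").mkdir(exist_ok=True)
    (out_dir / "transforms").mkdir(exist_ok=True)
    (out_dir / "waveforms").mkdir(exist_ok=True)
    for table, name in ((result.raw_table, "raw"), (result.reframed_table, "reframed")):
        if table is not None:
            table.to_long_csv(out_dir / "tables" / f"rmse_{name}.csv")
            (out_dir / "tables" / f"rmse_{name}.md").write_text(table.render())
    summary = {}
    for (ms, subject, knee), res in result.fits.items():
        rgio.save_reframe_result(
            res, out_dir / "transforms" / f"{ms.replace(' ', '_')}_{knee}.json",
            meta={"marker_set": ms, "subject": subject, "knee": knee})
        summary.setdefault(ms, []).append(list(res.fem_triplet) + list(res.tib_triplet))
    agg = {
        ms: {"mean_deg": np.mean(v, axis=0).round(4).tolist(),
             "sd_deg": (np.std(v, axis=0, ddof=1) if len(v) > 1
                        else np.zeros(6)).round(4).tolist()}
        for ms, v in summary.items()
    }
    (out_dir / "transforms" / "summary.json").write_text(json.dumps(
        {"axes": ["fem_x", "fem_y", "fem_z", "tib_x", "tib_y", "tib_z"],
         "per_set": agg}, indent=1))
    result.waveforms.to_csv(out_dir / "waveforms" / "mean_sd.csv", index=False)
    manifest.save(out_dir / "manifest.json")
    if manifest.make_plots:
        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        plot_mean_sd(result.waveforms, fig_dir / "mean_sd.png")


def plot_mean_sd(waveforms: pd.DataFrame, path) -> Path:
    """Three stacked panels (flexion, ab/adduction, int/external rotation),
    raw and reframed side by side, shaded +/- 1 SD bands, x-axis % gait cycle.

    Numeric assertions belong on the waveform table, not on pixels.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = [s for s in ("raw", "reframed") if (waveforms.stage == s).any()]
    fig, axes = plt.subplots(3, len(stages), figsize=(5 * len(stages), 9),
                             sharex=True, squeeze=False)
    labels = {"flexion": "Flexion [deg]", "adduction": "Ab/Adduction [deg]",
              "rotation": "Int/Ext Rotation [deg]"}
    for col, stage in enumerate(stages):
        for row, channel in enumerate(CHANNELS):
            ax = axes[row][col]
            sub = waveforms[(waveforms.stage == stage) & (waveforms.channel == channel)]
            for ms, grp in sub.groupby("marker_set"):
                grp = grp.sort_values("pct")
                ax.plot(grp.pct, grp.mean_deg, label=ms, lw=1.2)
                ax.fill_between(grp.pct, grp.mean_deg - grp.sd_deg,
                                grp.mean_deg + grp.sd_deg, alpha=0.15)
            if row == 0:
                ax.set_title(stage)
            if col == 0:
                ax.set_ylabel(labels[channel])
            if row == 2:
                ax.set_xlabel("% of gait cycle")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
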
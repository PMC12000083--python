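"""On-disk dialects: pose/angle CSVs with JSON sidecars, dataset directories,
YAML configs and JSON result payloads.

Pose series CSV columns: ``sample,time_s,seg,r11,...,r33`` with
``seg in {femur, tibia}``.  Angle series CSV columns:
``sample,pct_cycle,flex_deg,add_deg,introt_deg`` using the clinical display
sign for flexion (positive).  Each CSV has a ``*.meta.json`` sidecar carrying
knee id, side, trial, marker-set label, sampling rate, mirrored flag and
events.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import MarkerSetDataset, PoseTrial
from .reframe import ReframeConfig, ReframeResult
from .rotations import JointAngleSeries
from .synthetic import MisalignmentSpec, SyntheticConfig

__all__ = [
    "write_pose_trial", "read_pose_trial",
    "write_angle_series", "read_angle_series",
    "write_dataset", "read_dataset",
    "load_reframe_config", "save_reframe_config",
    "load_synthetic_config", "save_synthetic_config",
    "save_reframe_result",
]

_POSE_COLS = ["r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_pose_trial(trial: PoseTrial, path) -> Path:
    path = Path(path)
    n = trial.n_samples
    time_s = np.arange(n) / trial.rate_hz
    frames = []
    for seg, rots in (("femur", trial.femur), ("tibia", trial.tibia)):
        df = pd.DataFrame(rots.reshape(n, 9), columns=_POSE_COLS)
        df.insert(0, "seg", seg)
        df.insert(0, "time_s", time_s)
        df.insert(0, "sample", np.arange(n))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject": trial.subject, "knee": trial.knee, "side": trial.side,
        "trial": trial.trial, "marker_set": trial.marker_set,
        "rate_hz": trial.rate_hz, "mirrored": trial.mirrored,
        "events": list(trial.events),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_pose_trial(path) -> PoseTrial:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text())
    segs = {}
    for seg in ("femur", "tibia"):
        sub = df[df.seg == seg].sort_values("sample")
        segs[seg] = sub[_POSE_COLS].to_numpy().reshape(-1, 3, 3)
    return PoseTrial(
        femur=segs["femur"], tibia=segs["tibia"], rate_hz=float(meta["rate_hz"]),
        events=tuple(int(e) for e in meta["events"]),
        subject=meta["subject"], knee=meta["knee"], trial=int(meta["trial"]),
        marker_set=meta["marker_set"], side=meta["side"],
        mirrored=bool(meta["mirrored"]),
    )


def write_angle_series(series: JointAngleSeries, path, meta: Optional[dict] = None) -> Path:
    """Angle CSV in clinical display sign (flexion positive)."""
    path = Path(path)
    deg = series.angles_deg
    df = pd.DataFrame({
        "sample": np.arange(series.n_samples),
        "pct_cycle": series.domain if series.domain_kind == "percent"
        else np.full(series.n_samples, np.nan),
        "flex_deg": -deg[:, 0],
        "add_deg": deg[:, 1],
        "introt_deg": deg[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")
    if meta is not None:
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_angle_series(path) -> JointAngleSeries:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    deg = np.column_stack([-df.flex_deg, df.add_deg, df.introt_deg])
    if df.pct_cycle.notna().all():
        return JointAngleSeries.from_degrees(deg, df.pct_cycle.to_numpy(), "percent")
    return JointAngleSeries.from_degrees(deg, df["sample"].to_numpy(dtype=float), "frames")


# ---------------------------------------------------------------------------
# dataset directories
# ---------------------------------------------------------------------------

def write_dataset(ds: MarkerSetDataset, root) -> Path:
    """One directory per marker set; a manifest plus a ground-truth file."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for trial in ds:
        d = root / trial.marker_set.replace(" ", "_")
        d.mkdir(exist_ok=True)
        write_pose_trial(trial, d / f"{trial.subject}_{trial.knee}_t{trial.trial:02d}.csv")
    manifest = {
        "marker_sets": ds.marker_sets,
        "knees": ds.knees(),
        "trials": ds.trial_ids(),
        "misalignments": {k: [list(v[0]), list(v[1])] for k, v in ds.misalignments.items()},
    }
    cfg = ds.meta.get("config")
    if isinstance(cfg, SyntheticConfig):
        manifest["synthetic_config"] = _synthetic_to_dict(cfg)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if ds.truth:
        truth = {
            "|".join([s, k, str(t)]): series.angles_deg.tolist()
            for (s, k, t), series in ds.truth.items()
        }
        (root / "ground_truth.json").write_text(json.dumps(truth))
    return root


def read_dataset(root) -> MarkerSetDataset:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    ds = MarkerSetDataset(marker_sets=list(manifest["marker_sets"]))
    ds.misalignments = {k: (tuple(v[0]), tuple(v[1]))
                        for k, v in manifest.get("misalignments", {}).items()}
    for ms in ds.marker_sets:
        d = root / ms.replace(" ", "_")
        for csv in sorted(d.glob("*.csv")):
            ds.add(read_pose_trial(csv))
    truth_path = root / "ground_truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        for key, deg in raw.items():
            s, k, t = key.split("|")
            arr = np.asarray(deg, dtype=float)
            rate = next(iter(ds.trials.values())).rate_hz if ds.trials else None
            ds.truth[(s, k, int(t))] = JointAngleSeries.from_degrees(
                arr, np.arange(arr.shape[0], dtype=float), "frames", rate)
    return ds


# ---------------------------------------------------------------------------
# configs & results
# ---------------------------------------------------------------------------

def save_reframe_config(config: ReframeConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
    return path


def load_reframe_config(path) -> ReframeConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ReframeConfig(**data)


def _synthetic_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["marker_sets"] = {
        name: dataclasses.asdict(spec) for name, spec in config.marker_sets
    }
    return d


def save_synthetic_config(config: SyntheticConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_synthetic_to_dict(config), sort_keys=False))
    return path


def load_synthetic_config(source) -> SyntheticConfig:
    """Load from a YAML path or an already-parsed dict."""
    data = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    sets = data.pop("marker_sets", None)
    if sets is not None:
        data["marker_sets"] = tuple(
            (name, MisalignmentSpec(
                fem_deg=tuple(spec["fem_deg"]), tib_deg=tuple(spec["tib_deg"]),
                sta_amp_deg=float(spec.get("sta_amp_deg", 0.0)),
                sta_coupling=float(spec.get("sta_coupling", 0.5)),
            ))
            for name, spec in sets.items()
        )
    return SyntheticConfig(**data)


def save_reframe_result(result: ReframeResult, path, meta: Optional[dict] = None) -> Path:
    """Corrections as both matrix and Cardan triplet, costs and convergence."""
    payload = {
        "fem_triplet_deg": list(result.fem_triplet),
        "tib_triplet_deg": list(result.tib_triplet),
        "R_fem_corr": result.R_fem_corr.tolist(),
        "R_tib_corr": result.R_tib_corr.tolist(),
        "cost_initial_deg": result.cost_initial,
        "cost_final_deg": result.cost_final,
        "n_evaluations": result.n_evaluations,
        "converged": result.converged,
    }
    if meta:
        payload["meta"] = meta
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
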
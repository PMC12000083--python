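"""Waveform RMSE/RMS metrics and mean +/- SD aggregation into pairwise tables.

Comparisons operate on cycle-normalized angle waveforms in degrees.  The
pairwise table mirrors the shape used to report agreement between marker sets:
one cell per ordered marker-set pair and angle channel, holding the mean and
sample standard deviation of per-trial RMSE values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "rmse",
    "rms",
    "aggregate",
    "pairwise_table",
    "ComparisonTable",
    "PairingError",
    "CHANNELS",
]

CHANNELS = ("flexion", "adduction", "rotation")


class PairingError(KeyError):
    """A marker-set pair is missing matched (knee, trial) records."""

    def __init__(self, message: str, missing: Sequence[Tuple] = ()):  # noqa: D401
        super().__init__(message)
        self.missing = list(missing)


def rmse(a, b) -> float:
    """Root-mean-square error between two equal-length waveforms (degrees)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"waveform length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("waveforms must be non-empty")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rms(a) -> float:
    """Root-mean-square of a waveform, i.e. its RMSE versus a constant zero."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("waveform must be non-empty")
    return rmse(a, np.zeros_like(a))


def aggregate(values: pd.DataFrame, by: Sequence[str],
              value_col: str = "value") -> pd.DataFrame:
    """Mean +/- sample SD (ddof=1) of ``value_col`` per group.

    Groups of size 1 get SD = 0 and ``single_sample = True`` (with a warning),
    so single-trial inputs degrade gracefully instead of producing NaNs.
    """
    if values.empty:
        raise ValueError("nothing to aggregate")
    by = list(by)
    if not by:  # overall: pool everything into one group
        values = values.assign(_overall="all")
        by = ["_overall"]
    grouped = values.groupby(by, sort=True)[value_col]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    singles = out["n"] == 1
    out["single_sample"] = singles
    if singles.any():
        warnings.warn("group(s) of size 1: SD reported as 0", stacklevel=2)
        out.loc[singles, "sd"] = 0.0
    return out


def _per_trial_rmse(angles: Mapping[Tuple[str, str, int], np.ndarray],
                    stage: str) -> pd.DataFrame:
    """Per-trial RMSE for every ordered marker-set pair and channel.

    ``angles`` maps (marker_set, knee, trial) to an (n, 3) waveform in degrees
    with columns (flexion-or-alpha, adduction, rotation); RMSE is insensitive
    to a sign convention applied uniformly to both members of a pair.
    """
    sets = sorted({k[0] for k in angles})
    if len(sets) < 2:
        raise ValueError("need at least 2 marker sets for a pairwise table")
    by_set: Dict[str, Dict[Tuple[str, int], np.ndarray]] = {s: {} for s in sets}
    for (ms, knee, trial), wave in angles.items():
        by_set[ms][(knee, trial)] = np.asarray(wave, dtype=float)
    keys = sorted(by_set[sets[0]])
    rows = []
    for sa, sb in itertools.permutations(sets, 2):
        missing = [k for k in keys if k not in by_set[sa] or k not in by_set[sb]]
        extra = [k for k in by_set[sa] if k not in keys] + \
                [k for k in by_set[sb] if k not in keys]
        if missing or extra:
            raise PairingError(
                f"marker sets {sa!r}/{sb!r} lack matched knee/trial records",
                missing=missing + extra)
        for knee, trial in keys:
            wa, wb = by_set[sa][(knee, trial)], by_set[sb][(knee, trial)]
            for c, channel in enumerate(CHANNELS):
                rows.append({
                    "set_a": sa, "set_b": sb, "knee": knee, "trial": trial,
                    "channel": channel, "stage": stage,
                    "value": rmse(wa[:, c], wb[:, c]),
                })
    return pd.DataFrame(rows)


@dataclass
class ComparisonTable:
    """Pairwise RMSE table with two-level mean +/- SD aggregation.

    ``per_trial`` keeps the trial-level values; :meth:`overall` pools all
    trial-level values across knees, :meth:`per_knee` averages within each
    knee across its trials.
    """

    per_trial: pd.DataFrame
    stage: str

    def overall(self) -> pd.DataFrame:
        out = aggregate(self.per_trial, by=["set_a", "set_b", "channel"])
        out["stage"] = self.stage
        return out.rename(columns={"mean": "mean_deg", "sd": "sd_deg"})

    def per_knee(self) -> pd.DataFrame:
        out = aggregate(self.per_trial, by=["set_a", "set_b", "channel", "knee"])
        out["stage"] = self.stage
        return out.rename(columns={"mean": "mean_deg", "sd": "sd_deg"})

    def cell(self, set_a: str, set_b: str, channel: str) -> Tuple[float, float]:
        t = self.overall()
        row = t[(t.set_a == set_a) & (t.set_b == set_b) & (t.channel == channel)]
        if row.empty:
            raise KeyError((set_a, set_b, channel))
        return float(row.mean_deg.iloc[0]), float(row.sd_deg.iloc[0])

    def to_long_csv(self, path) -> None:
        self.overall()[["set_a", "set_b", "channel", "stage", "mean_deg", "sd_deg"]] \
            .to_csv(path, index=False)

    def render(self, fmt: str = "{:.1f} ± {:.1f}") -> str:
        """Markdown-style matrix of mean +/- SD cells, one block per channel."""
        t = self.overall()
        sets = sorted(set(t.set_a) | set(t.set_b))
        lines = [f"RMSE [deg] — stage: {self.stage}"]
        for channel in CHANNELS:
            lines.append(f"\n{channel}")
            lines.append("| vs | " + " | ".join(sets) + " |")
            lines.append("|---" * (len(sets) + 1) + "|")
            for sa in sets:
                cells = []
                for sb in sets:
                    if sa == sb:
                        cells.append("-")
                    else:
                        m, s = self.cell(sa, sb, channel)
                        cells.append(fmt.format(m, s))
                lines.append(f"| {sa} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def pairwise_table(angles: Mapping[Tuple[str, str, int], np.ndarray],
                   stage: str) -> ComparisonTable:
    """Build the pairwise RMSE table for one processing stage.

    Parameters
    ----------
    angles
        Mapping of (marker_set, knee, trial) to an (n, 3) waveform in degrees.
    stage
        ``'raw'`` or ``'reframed'`` — a label only; both stages use identical
        pairing logic.
    """
    return ComparisonTable(_per_trial_rmse(angles, stage), stage)
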
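"""Containers for study-shaped kinematic data: trials of segment poses keyed by
(subject, knee, trial, marker set), with optional synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .rotations import JointAngleSeries, MirrorStateError, mirror_left_to_right

__all__ = ["PoseTrial", "MarkerSetDataset", "TrialKey"]

#: (subject, knee, trial, marker_set)
TrialKey = Tuple[str, str, int, str]


@dataclass
class PoseTrial:
    """Femoral and tibial orientation series for one knee / trial / marker set.

    ``events`` are sample indices delimiting gait cycles (k+1 events span
    k cycles).  ``side`` records the anatomical side of origin; ``mirrored``
    flags data already reflected into right-knee convention.
    """

    femur: np.ndarray
    tibia: np.ndarray
    rate_hz: float
    events: Tuple[int, ...]
    subject: str
    knee: str
    trial: int
    marker_set: str
    side: str = "right"
    mirrored: bool = False

    def __post_init__(self):
        self.femur = np.asarray(self.femur, dtype=float)
        self.tibia = np.asarray(self.tibia, dtype=float)
        if self.femur.shape != self.tibia.shape or self.femur.ndim != 3:
            raise ValueError("femur/tibia must be equal-shape (n, 3, 3) stacks")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def n_samples(self) -> int:
        return self.femur.shape[0]

    def mirrored_copy(self) -> "PoseTrial":
        """Reflect a left-side trial into right-knee convention (x -> -x).

        Poses transform as ``R -> M R M`` with ``M = diag(-1, 1, 1)``, which
        preserves properness.  Mirroring twice is an error.
        """
        if self.side != "left":
            raise MirrorStateError(f"trial {self.key()} is not flagged as left side")
        if self.mirrored:
            raise MirrorStateError(f"trial {self.key()} is already mirrored")
        return replace(
            self,
            femur=mirror_left_to_right(self.femur, kind="poses"),
            tibia=mirror_left_to_right(self.tibia, kind="poses"),
            mirrored=True,
        )

    def key(self) -> TrialKey:
        return (self.subject, self.knee, self.trial, self.marker_set)


@dataclass
class MarkerSetDataset:
    """The study-shaped container: marker sets x knees x trials of pose series.

    ``truth`` and ``misalignments`` are populated only for synthetic data:
    the underlying joint-angle series per (subject, knee, trial) and the
    imposed constant (femoral, tibial) Cardan misalignment triplets (degrees)
    per marker set.
    """

    marker_sets: List[str]
    trials: Dict[TrialKey, PoseTrial] = field(default_factory=dict)
    truth: Dict[Tuple[str, str, int], JointAngleSeries] = field(default_factory=dict)
    misalignments: Dict[str, Tuple[Tuple[float, float, float],
                                   Tuple[float, float, float]]] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def add(self, trial: PoseTrial) -> None:
        self.trials[trial.key()] = trial

    def knees(self) -> List[Tuple[str, str]]:
        return sorted({(k[0], k[1]) for k in self.trials})

    def trial_ids(self) -> List[int]:
        return sorted({k[2] for k in self.trials})

    def get(self, subject: str, knee: str, trial: int, marker_set: str) -> PoseTrial:
        return self.trials[(subject, knee, trial, marker_set)]

    def __iter__(self) -> Iterator[PoseTrial]:
        return iter(self.trials[k] for k in sorted(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def validate_complete(self) -> None:
        """Check the full key cross product is present."""
        knees = self.knees()
        trials = self.trial_ids()
        missing = [
            (s, kn, t, ms)
            for (s, kn) in knees for t in trials for ms in self.marker_sets
            if (s, kn, t, ms) not in self.trials
        ]
        if missing:
            raise KeyError(f"dataset is missing {len(missing)} trial records, "
                           f"first: {missing[:3]}")
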
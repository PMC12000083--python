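"""Rotation algebra and Cardan joint-angle extraction for tibio-femoral kinematics.

Conventions
-----------
Segment frames are right-handed with the x-axis pointing laterally, the y-axis
anteriorly and the z-axis proximally.  Joint rotations describe the tibia
relative to the femur as an *intrinsic* X-then-Y-then-Z Cardan sequence:

* ``alpha_x`` — rotation about the mediolateral axis; positive is extension,
  so flexion is a negative rotation (clinical displays flip the sign).
* ``beta_y`` — rotation about the anteroposterior axis; positive is adduction.
* ``gamma_z`` — rotation about the longitudinal axis; positive is internal
  tibial rotation.

Left knees are mirrored (x-coordinates inverted) so that every knee can be
processed as a right knee.

Angles are stored in radians internally; every public interface speaks
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GimbalLockError",
    "MirrorStateError",
    "JointAngleSeries",
    "cardan_xyz_to_matrix",
    "matrix_to_cardan_xyz",
    "joint_rotation",
    "mirror_left_to_right",
    "compute_joint_angles",
    "to_clinical_display",
    "normalize_gait_cycle",
    "check_rotation",
]

#: |cos(beta_y)| below this triggers the degenerate-orientation signal.
GIMBAL_COS_TOL = 1e-7

#: Orthonormality / determinant tolerance for rotation matrices.
ROTATION_ATOL = 1e-9

#: Community-standard number of samples for a normalized gait cycle (0-100 %).
N_NORM_DEFAULT = 101

_MIRROR = np.diag([-1.0, 1.0, 1.0])


class GimbalLockError(ValueError):
    """Raised when |beta_y| is within tolerance of 90 degrees.

    Knee ab/adduction never approaches 90 deg, so hitting this signal
    indicates corrupt input rather than a physiological pose.  The exception
    carries the conventional resolution (``gamma_z`` assigned 0, the free
    rotation folded into ``alpha_x``) and, when raised from a series
    operation, the offending sample index.
    """

    def __init__(self, message: str, resolution: Optional[Tuple[float, float, float]] = None,
                 sample: Optional[int] = None):
        super().__init__(message)
        self.resolution = resolution
        self.sample = sample


class MirrorStateError(RuntimeError):
    """Raised when already-mirrored data is mirrored again."""


# ---------------------------------------------------------------------------
# elementary rotations
# ---------------------------------------------------------------------------

def _rx(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _ry(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 1, 1] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rz(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 2, 2] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def check_rotation(R: np.ndarray, atol: float = ROTATION_ATOL, name: str = "R") -> np.ndarray:
    """Validate that ``R`` is a proper orthonormal rotation (det = +1).

    Accepts a single ``(3, 3)`` matrix or a stack ``(..., 3, 3)``; returns the
    validated float array.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"{name} must have shape (..., 3, 3), got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError(f"{name} contains non-finite entries")
    eye = np.eye(3)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
    if err > atol:
        raise ValueError(f"{name} is not orthonormal (max deviation {err:.3e} > {atol:.1e})")
    det_err = np.abs(np.linalg.det(R) - 1.0).max()
    if det_err > atol:
        raise ValueError(f"{name} is not proper (det deviates by {det_err:.3e})")
    return R


# ---------------------------------------------------------------------------
# Cardan conversions
# ---------------------------------------------------------------------------

def cardan_xyz_to_matrix(angles_deg) -> np.ndarray:
    """Intrinsic X-Y-Z Cardan angles (degrees) to rotation matrix.

    Equals ``Rx(alpha) @ Ry(beta) @ Rz(gamma)``.  Accepts a triplet or a
    stacked array of triplets ``(..., 3)``.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) Cardan triplets, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("Cardan angles must be finite")
    rad = np.deg2rad(a)
    return _rx(rad[..., 0]) @ _ry(rad[..., 1]) @ _rz(rad[..., 2])


def _extract_cardan_rad(R: np.ndarray) -> np.ndarray:
    """Fast intrinsic-XYZ extraction in radians, no validation, no gimbal check.

    For R = Rx(a) Ry(b) Rz(c):
        R[0, 2] = sin b,  R[1, 2] = -sin a cos b,  R[2, 2] = cos a cos b,
        R[0, 1] = -cos b sin c,  R[0, 0] = cos b cos c.
    """
    alpha = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    beta = np.arctan2(R[..., 0, 2], np.hypot(R[..., 0, 0], R[..., 0, 1]))
    gamma = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    return np.stack([alpha, beta, gamma], axis=-1)


def _gimbal_cos(R: np.ndarray) -> np.ndarray:
    return np.hypot(R[..., 0, 0], R[..., 0, 1])


def matrix_to_cardan_xyz(R: np.ndarray, validate: bool = True) -> np.ndarray:
    """Rotation matrix to intrinsic X-Y-Z Cardan angles in degrees.

    The ``beta_y`` branch lies in [-90, 90] degrees.  Near gimbal lock
    (|cos beta_y| < 1e-7) a :class:`GimbalLockError` is raised carrying the
    conventional resolution (gamma_z = 0, the free rotation folded into
    alpha_x).
    """
    if validate:
        R = check_rotation(R)
    else:
        R = np.asarray(R, dtype=float)
    cb = _gimbal_cos(R)
    bad = cb < GIMBAL_COS_TOL
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        Rb = R.reshape(-1, 3, 3)[idx] if R.ndim > 2 else R
        sign = 1.0 if Rb[0, 2] >= 0 else -1.0
        # with gamma := 0, row 1 reads [sin(a +/- c'), cos(...), -+...] — fold into alpha
        alpha = float(np.degrees(np.arctan2(Rb[1, 0], Rb[1, 1])))
        resolution = (alpha, sign * 90.0, 0.0)
        raise GimbalLockError(
            f"beta_y within gimbal tolerance of {sign * 90:.0f} deg "
            f"(|cos beta| = {cb.min():.2e} < {GIMBAL_COS_TOL:.0e})",
            resolution=resolution,
            sample=idx if R.ndim > 2 else None,
        )
    return np.degrees(_extract_cardan_rad(R))


def joint_rotation(femur: np.ndarray, tibia: np.ndarray) -> np.ndarray:
    """Joint rotation of the tibia relative to the femur: ``femur.T @ tibia``.

    Both arguments are proper rotations (single or stacked); the result
    expresses the tibial axes in femoral coordinates.
    """
    femur = check_rotation(femur, name="femur")
    tibia = check_rotation(tibia, name="tibia")
    return np.swapaxes(femur, -1, -2) @ tibia


def mirror_left_to_right(data: np.ndarray, kind: Optional[str] = None) -> np.ndarray:
    """Mirror left-side data about the sagittal plane (x -> -x).

    ``kind='points'`` negates the x-coordinate of ``(..., 3)`` points;
    ``kind='poses'`` conjugates ``(..., 3, 3)`` orientations by
    ``M = diag(-1, 1, 1)`` (``R -> M R M``), which preserves det = +1.  If
    ``kind`` is omitted it is inferred from the trailing shape.

    Mirrored-state bookkeeping (rejecting double mirroring) lives on the
    trial containers in :mod:`reframe_gait.dataset`.
    """
    arr = np.asarray(data, dtype=float)
    if kind is None:
        if arr.shape[-2:] == (3, 3):
            kind = "poses"
        elif arr.shape[-1] == 3:
            kind = "points"
        else:
            raise ValueError(f"cannot infer mirror kind from shape {arr.shape}")
    if kind == "poses":
        return _MIRROR @ arr @ _MIRROR
    if kind == "points":
        out = arr.copy()
        out[..., 0] *= -1.0
        return out
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# angle series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointAngleSeries:
    """Time series of Cardan triplets for one knee / trial / marker set.

    ``angles_rad`` has shape ``(n, 3)`` with columns (alpha_x, beta_y,
    gamma_z), unwrapped and in radians.  ``domain`` is either a raw frame
    index (``domain_kind='frames'``, with ``rate_hz`` set) or percent of the
    gait cycle on [0, 100] (``domain_kind='percent'``).
    """

    angles_rad: np.ndarray
    domain: np.ndarray
    domain_kind: str = "frames"
    rate_hz: Optional[float] = None

    def __post_init__(self):
        angles = np.asarray(self.angles_rad, dtype=float)
        domain = np.asarray(self.domain, dtype=float)
        if angles.ndim != 2 or angles.shape[1] != 3:
            raise ValueError(f"angles must be (n, 3), got {angles.shape}")
        if angles.shape[0] < 2:
            raise ValueError("a series needs at least 2 samples")
        if domain.shape != (angles.shape[0],):
            raise ValueError("domain length must match the number of samples")
        if np.any(np.diff(domain) <= 0):
            raise ValueError("domain must be strictly increasing")
        if self.domain_kind not in ("frames", "percent"):
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        if self.domain_kind == "percent" and not (
            abs(domain[0]) < 1e-9 and abs(domain[-1] - 100.0) < 1e-9
        ):
            raise ValueError("percent domain must span 0-100 inclusive")
        object.__setattr__(self, "angles_rad", angles)
        object.__setattr__(self, "domain", domain)

    @classmethod
    def from_degrees(cls, angles_deg, domain=None, domain_kind: str = "frames",
                     rate_hz: Optional[float] = None) -> "JointAngleSeries":
        angles_deg = np.asarray(angles_deg, dtype=float)
        if domain is None:
            domain = np.arange(angles_deg.shape[0], dtype=float)
        return cls(np.deg2rad(angles_deg), np.asarray(domain, dtype=float),
                   domain_kind, rate_hz)

    @property
    def n_samples(self) -> int:
        return self.angles_rad.shape[0]

    @property
    def angles_deg(self) -> np.ndarray:
        return np.degrees(self.angles_rad)

    @property
    def alpha_deg(self) -> np.ndarray:
        return np.degrees(self.angles_rad[:, 0])

    @property
    def beta_deg(self) -> np.ndarray:
        return np.degrees(self.angles_rad[:, 1])

    @property
    def gamma_deg(self) -> np.ndarray:
        return np.degrees(self.angles_rad[:, 2])


def compute_joint_angles(femur_series: np.ndarray, tibia_series: np.ndarray,
                         rate_hz: Optional[float] = None,
                         unwrap: bool = True) -> JointAngleSeries:
    """Per-sample Cardan angles of the tibia relative to the femur.

    Both inputs are stacked rotations ``(n, 3, 3)``, time-aligned and equal
    length.  Angles are unwrapped per channel across the +/-180 deg boundary
    so smooth motions yield smooth waveforms.
    """
    femur_series = np.asarray(femur_series, dtype=float)
    tibia_series = np.asarray(tibia_series, dtype=float)
    if femur_series.shape != tibia_series.shape:
        raise ValueError(
            f"femur/tibia series length mismatch: {femur_series.shape} vs {tibia_series.shape}")
    J = joint_rotation(femur_series, tibia_series)
    cb = _gimbal_cos(J)
    if np.any(cb < GIMBAL_COS_TOL):
        idx = int(np.argmax(cb < GIMBAL_COS_TOL))
        try:
            matrix_to_cardan_xyz(J[idx], validate=False)
        except GimbalLockError as exc:
            raise GimbalLockError(
                f"gimbal-locked sample at index {idx}: {exc}",
                resolution=exc.resolution, sample=idx) from exc
    rad = _extract_cardan_rad(J)
    if unwrap:
        rad = np.unwrap(rad, axis=0)
    n = rad.shape[0]
    return JointAngleSeries(rad, np.arange(n, dtype=float), "frames", rate_hz)


def to_clinical_display(series: JointAngleSeries) -> np.ndarray:
    """Display triplets in degrees with flexion shown positive.

    Flexion is a negative rotation about the laterally pointing x-axis; for
    figures and exports the first column's sign is flipped.  The stored series
    is unchanged.
    """
    out = series.angles_deg.copy()
    out[:, 0] *= -1.0
    return out


def normalize_gait_cycle(series: JointAngleSeries, event_indices: Sequence[int],
                         n_norm: int = N_NORM_DEFAULT) -> List[JointAngleSeries]:
    """Resample each gait cycle to ``n_norm`` points on [0, 100] percent.

    ``event_indices`` are sample indices delimiting cycles (k+1 events ->
    k cycles); channels are linearly interpolated on the unwrapped radians.
    """
    events = np.asarray(event_indices, dtype=float)
    if events.ndim != 1 or events.size < 2:
        raise ValueError("need at least 2 event indices delimiting one cycle")
    if np.any(np.diff(events) <= 0):
        raise ValueError("event indices must be strictly increasing")
    if events[0] < series.domain[0] - 1e-9 or events[-1] > series.domain[-1] + 1e-9:
        raise ValueError("event indices fall outside the series domain")
    pct = np.linspace(0.0, 100.0, n_norm)
    cycles = []
    for e0, e1 in zip(events[:-1], events[1:]):
        grid = np.linspace(e0, e1, n_norm)
        resampled = np.column_stack([
            np.interp(grid, series.domain, series.angles_rad[:, k]) for k in range(3)
        ])
        cycles.append(JointAngleSeries(resampled, pct.copy(), "percent", None))
    return cycles
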
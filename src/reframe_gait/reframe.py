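"""REFRAME: constant re-orientation of segment frames to minimize crosstalk.

Two sets of knee kinematics recorded with different marker sets can describe
the same underlying motion through differently oriented segment frames, which
shows up as spurious ab/adduction and axial-rotation signal (crosstalk).
REFRAME searches for one constant re-orientation of the femoral frame and one
of the tibial frame — each applied relative to the segment it represents —
that minimize a weighted cost:

    J = w_add * RMS(beta_y) + w_introt * RMS(gamma_z)
        + w_flex * RMSE(alpha_x, reference flexion)

with default weights 1 / 1 / 0.2.  The flexion term keeps the corrected
signals clinically interpretable by tying flexion to a reference dataset;
re-orientation of the femoral frame about the flexion axis can additionally
be locked or bounded.  The corrected joint rotation at sample t is

    T_t'  =  R_fem_corr^T  @  T_t  @  R_tib_corr

and the corrections are reported as intrinsic X-Y-Z Cardan triplets around
the raw segment axes (x lateral, y anterior, z proximal).

The optimizer is a deterministic derivative-free simplex search (Nelder-Mead)
over the 4-6 Cardan correction parameters, started from identity plus the
best points of a fixed coarse lattice on the out-of-sagittal parameters to
escape local minima, followed by a polish restart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .rotations import (
    JointAngleSeries,
    _extract_cardan_rad,
    cardan_xyz_to_matrix,
    check_rotation,
    matrix_to_cardan_xyz,
)

__all__ = [
    "ReframeConfig",
    "ReframeResult",
    "apply_frame_corrections",
    "reframe_cost",
    "optimize",
    "report_transform",
]

_FEM_X_MODES = ("penalized", "locked", "bounded")


@dataclass(frozen=True)
class ReframeConfig:
    """Cost weights, constraints and optimizer settings for REFRAME.

    ``femoral_x_mode`` governs re-orientation of the femoral frame about the
    flexion (x) axis: ``'penalized'`` leaves it free, discouraged only through
    the flexion-RMSE term; ``'locked'`` fixes it to zero; ``'bounded'`` limits
    it to +/- ``femoral_x_limit_deg``.
    """

    w_add: float = 1.0
    w_introt: float = 1.0
    w_flex: float = 0.2
    reference_label: str = "PiG"
    femoral_x_mode: str = "penalized"
    femoral_x_limit_deg: float = 15.0
    optimize_femoral: bool = True
    optimize_tibial: bool = True
    tol: float = 1e-8
    max_evals: int = 10000
    multistart_span_deg: float = 12.0
    multistart_step_deg: float = 6.0
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.w_add < 0 or self.w_introt < 0 or self.w_flex < 0:
            raise ValueError("weights must be non-negative")
        if self.w_add == 0 and self.w_introt == 0:
            raise ValueError("at least one of w_add, w_introt must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.femoral_x_mode not in _FEM_X_MODES:
            raise ValueError(f"femoral_x_mode must be one of {_FEM_X_MODES}")
        if not (self.optimize_femoral or self.optimize_tibial):
            raise ValueError("nothing to optimize: both segments disabled")

    def param_names(self) -> List[str]:
        names: List[str] = []
        if self.optimize_femoral:
            if self.femoral_x_mode != "locked":
                names.append("fem_x")
            names += ["fem_y", "fem_z"]
        if self.optimize_tibial:
            names += ["tib_x", "tib_y", "tib_z"]
        return names


@dataclass
class ReframeResult:
    """Constant corrections plus the optimized signals and diagnostics.

    ``fem_triplet`` / ``tib_triplet`` report each correction as an intrinsic
    X-Y-Z Cardan triplet in degrees around the raw segment axes.
    ``cost_initial`` is the cost at identity corrections.
    """

    R_fem_corr: np.ndarray
    R_tib_corr: np.ndarray
    fem_triplet: Tuple[float, float, float]
    tib_triplet: Tuple[float, float, float]
    optimized: JointAngleSeries
    cost_initial: float
    cost_final: float
    n_evaluations: int
    converged: bool


# ---------------------------------------------------------------------------
# cost machinery
# ---------------------------------------------------------------------------

def _corrections_from_params(params_deg: np.ndarray,
                             config: ReframeConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Map a flat parameter vector (degrees) to the two correction matrices."""
    names = config.param_names()
    vals = dict(zip(names, np.atleast_1d(np.asarray(params_deg, dtype=float))))
    fem = np.array([vals.get("fem_x", 0.0), vals.get("fem_y", 0.0), vals.get("fem_z", 0.0)])
    tib = np.array([vals.get("tib_x", 0.0), vals.get("tib_y", 0.0), vals.get("tib_z", 0.0)])
    return cardan_xyz_to_matrix(fem), cardan_xyz_to_matrix(tib)


def apply_frame_corrections(joint_rotations: np.ndarray,
                            R_fem_corr: np.ndarray,
                            R_tib_corr: np.ndarray,
                            domain: Optional[np.ndarray] = None,
                            domain_kind: str = "frames",
                            rate_hz: Optional[float] = None) -> JointAngleSeries:
    """Re-extract joint angles after constant frame corrections.

    ``joint_rotations`` is the raw joint-rotation series ``(n, 3, 3)``
    (tibia relative to femur); the corrected series is
    ``R_fem_corr^T @ T_t @ R_tib_corr`` for every sample, with the same
    constant corrections across the whole series.
    """
    T = np.asarray(joint_rotations, dtype=float)
    if T.ndim != 3 or T.shape[0] < 1:
        raise ValueError("joint_rotations must be a non-empty (n, 3, 3) stack")
    Rf = check_rotation(R_fem_corr, name="R_fem_corr")
    Rt = check_rotation(R_tib_corr, name="R_tib_corr")
    corrected = Rf.T @ T @ Rt
    rad = np.unwrap(_extract_cardan_rad(corrected), axis=0)
    if domain is None:
        domain = np.arange(T.shape[0], dtype=float)
    return JointAngleSeries(rad, domain, domain_kind, rate_hz)


def _cost_from_channels(alpha_deg: np.ndarray, beta_deg: np.ndarray,
                        gamma_deg: np.ndarray, reference_flexion_deg: np.ndarray,
                        config: ReframeConfig) -> np.ndarray:
    rms_b = np.sqrt(np.mean(beta_deg ** 2, axis=-1))
    rms_g = np.sqrt(np.mean(gamma_deg ** 2, axis=-1))
    rmse_a = np.sqrt(np.mean((alpha_deg - reference_flexion_deg) ** 2, axis=-1))
    return config.w_add * rms_b + config.w_introt * rms_g + config.w_flex * rmse_a


def reframe_cost(angles: JointAngleSeries, reference_flexion_deg,
                 config: ReframeConfig = ReframeConfig()) -> float:
    """Weighted crosstalk cost of an angle series, in degrees.

    ``reference_flexion_deg`` is the reference dataset's alpha_x channel
    (internal sign convention, degrees), same length as the series.
    """
    ref = np.asarray(reference_flexion_deg, dtype=float)
    if ref.shape != (angles.n_samples,):
        raise ValueError(
            f"reference flexion length {ref.shape} != series length {angles.n_samples}")
    deg = angles.angles_deg
    return float(_cost_from_channels(deg[:, 0], deg[:, 1], deg[:, 2], ref, config))


def _batch_cost(T: np.ndarray, params_deg: np.ndarray, config: ReframeConfig,
                ref_deg: np.ndarray, chunk: int = 40000) -> np.ndarray:
    """Vectorized cost for a batch of parameter vectors ``(g, k)``."""
    g = params_deg.shape[0]
    names = config.param_names()
    fem = np.zeros((g, 3))
    tib = np.zeros((g, 3))
    for j, name in enumerate(names):
        seg, axis = name.split("_")
        (fem if seg == "fem" else tib)[:, "xyz".index(axis)] = params_deg[:, j]
    Rf = cardan_xyz_to_matrix(fem)
    Rt = cardan_xyz_to_matrix(tib)
    n = T.shape[0]
    costs = np.empty(g)
    step = max(1, chunk // max(n, 1))
    for lo in range(0, g, step):
        hi = min(lo + step, g)
        corrected = Rf[lo:hi].transpose(0, 2, 1)[:, None] @ T @ Rt[lo:hi, None]
        rad = _extract_cardan_rad(corrected)
        deg = np.degrees(rad)
        costs[lo:hi] = _cost_from_channels(deg[..., 0], deg[..., 1], deg[..., 2],
                                           ref_deg, config)
    return costs


def _bound_penalty(params_deg: np.ndarray, config: ReframeConfig) -> float:
    if config.femoral_x_mode != "bounded" or not config.optimize_femoral:
        return 0.0
    names = config.param_names()
    if "fem_x" not in names:
        return 0.0
    x = params_deg[names.index("fem_x")]
    excess = max(0.0, abs(x) - config.femoral_x_limit_deg)
    return 1e6 * excess ** 2


def _multistart_points(config: ReframeConfig) -> np.ndarray:
    """Fixed coarse lattice on the out-of-sagittal (y/z) parameters."""
    names = config.param_names()
    span, step = config.multistart_span_deg, config.multistart_step_deg
    grid = np.arange(-span, span + 0.5 * step, step)
    axes = [grid if name.endswith(("_y", "_z")) else np.array([0.0]) for name in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def optimize(joint_rotations: np.ndarray, reference_flexion_deg,
             config: ReframeConfig = ReframeConfig(),
             domain: Optional[np.ndarray] = None,
             domain_kind: str = "frames",
             rate_hz: Optional[float] = None) -> ReframeResult:
    """Find constant frame corrections minimizing the REFRAME cost.

    Deterministic given the config: identity plus the best points of a fixed
    multistart lattice seed a Nelder-Mead search; the best minimum is polished
    by one restart.  Non-convergence within ``max_evals`` returns a result
    with ``converged=False`` rather than failing silently.
    """
    T = np.asarray(joint_rotations, dtype=float)
    if T.ndim != 3 or T.shape[0] < 1:
        raise ValueError("joint_rotations must be a non-empty (n, 3, 3) stack")
    check_rotation(T, name="joint_rotations")
    ref = np.asarray(reference_flexion_deg, dtype=float)
    if ref.shape != (T.shape[0],):
        raise ValueError("reference flexion length must match the series")
    names = config.param_names()
    k = len(names)

    def cost(p: np.ndarray) -> float:
        Rf, Rt = _corrections_from_params(p, config)
        corrected = Rf.T @ T @ Rt
        deg = np.degrees(_extract_cardan_rad(corrected))
        return float(_cost_from_channels(deg[:, 0], deg[:, 1], deg[:, 2], ref, config)
                     ) + _bound_penalty(p, config)

    cost_initial = cost(np.zeros(k))
    n_evals = 1

    lattice = _multistart_points(config)
    lattice_costs = _batch_cost(T, lattice, config, ref)
    n_evals += lattice.shape[0]
    order = np.argsort(lattice_costs, kind="stable")
    starts = [np.zeros(k)]
    for idx in order[: max(0, config.n_restarts - 1)]:
        p = lattice[idx]
        if not any(np.allclose(p, s) for s in starts):
            starts.append(p)

    def nm(x0: np.ndarray, step_deg: float):
        # explicit initial simplex: scipy's default degenerates to ~2.5e-4 deg
        # steps around a zero start, crawling toward distant minima
        simplex = np.vstack([x0, x0 + step_deg * np.eye(k)])
        return minimize(cost, x0, method="Nelder-Mead",
                        options=dict(fatol=config.tol, xatol=1e-6,
                                     maxfev=config.max_evals,
                                     initial_simplex=simplex))

    best = None
    success = False
    for x0 in starts:
        res = nm(x0, 2.0)
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
            success = bool(res.success)
    # polish: restart a small simplex at the incumbent minimum
    res = nm(best.x, 0.05)
    n_evals += res.nfev
    if res.fun <= best.fun:
        best = res
        success = success or bool(res.success)

    Rf, Rt = _corrections_from_params(best.x, config)
    optimized = apply_frame_corrections(T, Rf, Rt, domain=domain,
                                        domain_kind=domain_kind, rate_hz=rate_hz)
    converged = bool(success and best.fun <= cost_initial + config.tol)
    return ReframeResult(
        R_fem_corr=Rf,
        R_tib_corr=Rt,
        fem_triplet=report_transform(Rf),
        tib_triplet=report_transform(Rt),
        optimized=optimized,
        cost_initial=cost_initial,
        cost_final=float(best.fun),
        n_evaluations=n_evals,
        converged=converged,
    )


def report_transform(R_corr: np.ndarray) -> Tuple[float, float, float]:
    """Report a correction as an intrinsic X-Y-Z Cardan triplet in degrees.

    Rotations are given around the raw axes of the segment frame: x lateral,
    y anterior, z proximal.  Inverse of :func:`cardan_xyz_to_matrix`.
    """
    trip = matrix_to_cardan_xyz(R_corr)
    return (float(trip[0]), float(trip[1]), float(trip[2]))
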
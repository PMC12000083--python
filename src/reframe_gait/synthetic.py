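"""Synthetic multi-marker-set gait study with known ground truth.

One underlying tibio-femoral motion per knee and trial is observed through
several virtual "marker sets" that differ by constant misorientations of the
femoral and tibial frames (the crosstalk mechanism REFRAME corrects), plus an
optional flexion-coupled soft-tissue-artifact (STA) perturbation.  The
defaults emulate a treadmill-gait study: 15 subjects x 2 knees x 9 steps
captured at 200 Hz through 5 marker sets, with misalignment presets of the
magnitudes reported for Plug-in-Gait-family and cylinder-fit marker sets
(longitudinal offsets up to ~15 deg, a few degrees about the other axes).
The presets are configuration, not ground-truth claims about any real system.

Every stage stores its ground truth, so pipeline recovery can be checked
exactly: with identity misalignments and STA off, re-extracted joint angles
reproduce the generator's waveforms to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dataset import MarkerSetDataset, PoseTrial
from .rotations import JointAngleSeries, cardan_xyz_to_matrix, mirror_left_to_right

__all__ = [
    "MisalignmentSpec",
    "SyntheticConfig",
    "HarmonicWaveform",
    "generate_base_motion",
    "observe_through_marker_set",
    "build_study",
    "default_marker_sets",
]


@dataclass(frozen=True)
class MisalignmentSpec:
    """Constant frame misorientation of one marker set, plus its STA model.

    ``fem_deg`` / ``tib_deg`` are intrinsic X-Y-Z Cardan triplets (degrees)
    post-multiplied onto the nominal segment orientations.  ``sta_amp_deg``
    scales a zero-mean time-varying perturbation whose amplitude follows
    flexion through ``sta_coupling`` (1 = fully flexion-coupled, 0 = pure
    low-frequency noise).
    """

    fem_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    tib_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sta_amp_deg: float = 0.0
    sta_coupling: float = 0.5


def default_marker_sets(sta_amp_deg: float = 0.5) -> Dict[str, MisalignmentSpec]:
    """Five marker-set presets patterned on reported transformation magnitudes.

    Longitudinal (z) offsets dominate and differ most between the
    Plug-in-Gait variants and the knee-alignment-device set; the cylinder-fit
    set carries the largest flexion-axis offset but, modelling its rigid-body
    post-processing, no STA.
    """
    return {
        "PiG": MisalignmentSpec((-0.6, 4.1, -14.3), (-1.0, 2.0, -8.2), sta_amp_deg, 0.6),
        "PiG wand": MisalignmentSpec((-2.9, 1.1, -2.7), (-1.5, 0.8, -3.5), sta_amp_deg, 0.5),
        "MA": MisalignmentSpec((-3.0, 1.2, -2.8), (-1.4, 0.9, -3.6), sta_amp_deg, 0.5),
        "KAD": MisalignmentSpec((-1.4, 0.6, -6.0), (-2.0, 1.0, -12.1), sta_amp_deg, 0.5),
        "MiKneeSoTA": MisalignmentSpec((-8.2, 5.3, 0.9), (1.0, -0.5, 0.5), 0.0, 0.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design, waveform and noise parameters for the generator.

    Counts follow the emulated protocol (15 subjects, both knees, nine
    consecutive steps at 200 Hz and ~4 km/h treadmill speed, hence ~1.1 s
    cycles).  Waveform parameters shape a gait-like flexion curve (stance
    flexion wave plus a ~60 deg swing peak) represented by a truncated
    Fourier series; ab/adduction and int/external rotation ground-truth
    amplitudes default to a few degrees.  ``trial_amp_sd`` is the fractional
    SD of per-trial amplitude variability.  A fixed seed makes output
    byte-identical across runs.
    """

    n_subjects: int = 15
    knees_per_subject: int = 2
    trials_per_knee: int = 9
    rate_hz: float = 200.0
    cycle_duration_s: float = 1.1
    n_harmonics: int = 12
    stance_peak_deg: float = 20.0
    swing_peak_deg: float = 60.0
    adduction_amp_deg: float = 2.0
    introt_amp_deg: float = 4.0
    trial_amp_sd: float = 0.03
    marker_sets: Tuple[Tuple[str, MisalignmentSpec], ...] = tuple(
        default_marker_sets().items())
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.knees_per_subject, self.trials_per_knee) < 1:
            raise ValueError("all design counts must be >= 1")
        if min(self.stance_peak_deg, self.swing_peak_deg,
               self.adduction_amp_deg, self.introt_amp_deg) < 0:
            raise ValueError("amplitudes must be non-negative")

    def marker_set_dict(self) -> Dict[str, MisalignmentSpec]:
        return dict(self.marker_sets)

    def without_sta(self) -> "SyntheticConfig":
        """Copy with all soft-tissue-artifact amplitudes set to zero."""
        sets = tuple((name, replace(spec, sta_amp_deg=0.0))
                     for name, spec in self.marker_sets)
        return replace(self, marker_sets=sets)

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.rate_hz * self.cycle_duration_s))


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

class HarmonicWaveform:
    """Periodic waveform represented by a truncated Fourier series on [0, 1).

    Built by projecting a smooth closed-form shape onto ``n_harmonics``
    harmonics and anchoring the value at cycle start to zero (gait curves are
    referenced to heel strike), so that compositions of channel waveforms are
    exactly the identity rotation at the start of every cycle.
    """

    def __init__(self, mean: float, cos_coef: np.ndarray, sin_coef: np.ndarray):
        self.mean = float(mean)
        self.cos_coef = np.asarray(cos_coef, dtype=float)
        self.sin_coef = np.asarray(sin_coef, dtype=float)

    @classmethod
    def project(cls, fn, n_harmonics: int, n_grid: int = 2048,
                anchor_zero: bool = True) -> "HarmonicWaveform":
        s = np.arange(n_grid) / n_grid
        y = np.asarray(fn(s), dtype=float)
        spec = np.fft.rfft(y) / n_grid
        mean = spec[0].real
        k = np.arange(1, n_harmonics + 1)
        cos_coef = 2.0 * spec[1:n_harmonics + 1].real
        sin_coef = -2.0 * spec[1:n_harmonics + 1].imag
        wf = cls(mean, cos_coef, sin_coef)
        if anchor_zero:
            wf.mean -= wf(0.0)
        return wf

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        k = np.arange(1, self.cos_coef.size + 1)
        phase = 2.0 * np.pi * np.multiply.outer(s, k)
        return (self.mean
                + np.cos(phase) @ self.cos_coef
                + np.sin(phase) @ self.sin_coef)


def _vm_bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth periodic bump (von-Mises shaped), peak 1 at ``center``."""
    kappa = 1.0 / (2.0 * np.pi * width) ** 2 * 2.0 * np.pi ** 2
    return np.exp(kappa * (np.cos(2.0 * np.pi * (s - center)) - 1.0))


def _waveforms(config: SyntheticConfig) -> Dict[str, HarmonicWaveform]:
    """Channel waveforms in display units (flexion positive), degrees."""
    H = config.n_harmonics

    def flex_shape(s):
        return (config.stance_peak_deg * _vm_bump(s, 0.15, 0.10)
                + config.swing_peak_deg * _vm_bump(s, 0.72, 0.11))

    def add_shape(s):
        return config.adduction_amp_deg * (
            np.sin(2.0 * np.pi * s) + 0.3 * np.sin(4.0 * np.pi * s))

    def rot_shape(s):
        return config.introt_amp_deg * (
            -np.sin(2.0 * np.pi * s) + 0.25 * np.sin(4.0 * np.pi * s))

    return {
        "flexion": HarmonicWaveform.project(flex_shape, H),
        "adduction": HarmonicWaveform.project(add_shape, H),
        "rotation": HarmonicWaveform.project(rot_shape, H),
    }


def generate_base_motion(config: SyntheticConfig,
                         rng: np.random.Generator) -> List[JointAngleSeries]:
    """Ground-truth joint-angle series for one knee, one per trial.

    Each trial spans one gait cycle (both endpoints included).  Per-trial
    variability scales each channel's amplitude by ``N(1, trial_amp_sd)``.
    Flexion is stored as a negative alpha_x per the sign convention.
    """
    waves = _waveforms(config)
    n = config.samples_per_cycle
    s = np.arange(n + 1) / n  # one cycle inclusive of both endpoints
    out = []
    for _ in range(config.trials_per_knee):
        scale = rng.normal(1.0, config.trial_amp_sd, size=3) if config.trial_amp_sd > 0 \
            else np.ones(3)
        alpha = -waves["flexion"](s) * scale[0]
        beta = waves["adduction"](s) * scale[1]
        gamma = waves["rotation"](s) * scale[2]
        angles_deg = np.column_stack([alpha, beta, gamma])
        out.append(JointAngleSeries.from_degrees(
            angles_deg, np.arange(n + 1, dtype=float), "frames", config.rate_hz))
    return out


def _femur_world_motion(s: np.ndarray) -> np.ndarray:
    """Smooth lab-frame femoral motion, so joint extraction is exercised with
    a non-identity common rotation (the joint angles are invariant to it)."""
    ang = np.column_stack([
        20.0 + 8.0 * np.sin(2.0 * np.pi * s),   # thigh pitch about x
        2.0 * np.sin(2.0 * np.pi * s + 0.7),    # lean about y
        3.0 * np.sin(2.0 * np.pi * s + 1.3),    # transverse about z
    ])
    return cardan_xyz_to_matrix(ang)


def _sta_rotation(n: int, flexion_norm: np.ndarray, spec: MisalignmentSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean time-varying perturbation rotation about a random fixed axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    # low-frequency noise: 3 random-phase harmonics of the cycle
    s = np.arange(n) / max(n - 1, 1)
    noise = np.zeros(n)
    for k in (1, 2, 3):
        amp = rng.normal(0.0, 0.5)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        noise += amp * np.sin(2.0 * np.pi * k * s + phase)
    angle = spec.sta_amp_deg * (spec.sta_coupling * flexion_norm
                                + (1.0 - spec.sta_coupling) * noise)
    angle = angle - angle.mean()
    rad = np.deg2rad(angle)
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    sin_a = np.sin(rad)[:, None, None]
    cos_a = np.cos(rad)[:, None, None]
    return np.eye(3) + sin_a * K + (1.0 - cos_a) * (K @ K)


def observe_through_marker_set(true_angles: JointAngleSeries,
                               spec: MisalignmentSpec,
                               rng: Optional[np.random.Generator] = None
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Femoral and tibial pose series realizing ``true_angles`` as seen by one
    marker set.

    Nominal segment poses reproduce the true joint rotation exactly; each
    segment's orientation is then post-multiplied by the marker set's constant
    misalignment, and (if ``sta_amp_deg > 0``) by a zero-mean time-varying STA
    rotation whose amplitude follows flexion.
    """
    T_true = cardan_xyz_to_matrix(true_angles.angles_deg)
    n = true_angles.n_samples
    s = np.arange(n) / max(n - 1, 1)
    W = _femur_world_motion(s)
    femur = W.copy()
    tibia = W @ T_true
    Mf = cardan_xyz_to_matrix(np.asarray(spec.fem_deg, dtype=float))
    Mt = cardan_xyz_to_matrix(np.asarray(spec.tib_deg, dtype=float))
    femur = femur @ Mf
    tibia = tibia @ Mt
    if spec.sta_amp_deg > 0.0:
        if rng is None:
            raise ValueError("an rng is required when STA is enabled")
        flex_norm = -true_angles.alpha_deg
        peak = np.abs(flex_norm).max()
        flex_norm = flex_norm / peak if peak > 0 else flex_norm
        femur = femur @ _sta_rotation(n, flex_norm, spec, rng)
        tibia = tibia @ _sta_rotation(n, flex_norm, spec, rng)
    return femur, tibia


def build_study(config: SyntheticConfig) -> MarkerSetDataset:
    """Assemble the full marker-sets x knees x trials synthetic study.

    Each subject's second knee is a left knee: its poses are generated in
    left-side coordinates and passed through the mirroring step, so the
    dataset exercises the left-to-right convention end to end.  The
    ground-truth block stores the underlying joint angles (right-knee
    convention) and the imposed misalignment constants.
    """
    specs = config.marker_set_dict()
    ds = MarkerSetDataset(marker_sets=list(specs))
    ds.misalignments = {name: (spec.fem_deg, spec.tib_deg)
                        for name, spec in specs.items()}
    ds.meta["config"] = config
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    sides = ["right", "left"] * ((config.knees_per_subject + 1) // 2)
    n_cyc = config.samples_per_cycle
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        knee_seeds = subject_seeds[i].spawn(config.knees_per_subject)
        for j in range(config.knees_per_subject):
            side = sides[j]
            knee = f"{subject}_{side[0].upper()}"
            knee_rng = np.random.default_rng(knee_seeds[j])
            truths = generate_base_motion(config, knee_rng)
            sta_seeds = knee_seeds[j].spawn(config.trials_per_knee)
            for t, truth in enumerate(truths, start=1):
                ds.truth[(subject, knee, t)] = truth
                trial_rng = np.random.default_rng(sta_seeds[t - 1])
                for name, spec in specs.items():
                    femur, tibia = observe_through_marker_set(truth, spec, trial_rng)
                    if side == "left":
                        # express in left-side coordinates, then mirror back
                        trial = PoseTrial(
                            femur=mirror_left_to_right(femur, kind="poses"),
                            tibia=mirror_left_to_right(tibia, kind="poses"),
                            rate_hz=config.rate_hz,
                            events=(0, n_cyc),
                            subject=subject, knee=knee, trial=t,
                            marker_set=name, side="left", mirrored=False,
                        ).mirrored_copy()
                    else:
                        trial = PoseTrial(
                            femur=femur, tibia=tibia, rate_hz=config.rate_hz,
                            events=(0, n_cyc),
                            subject=subject, knee=knee, trial=t,
                            marker_set=name, side="right", mirrored=False,
                        )
                    ds.add(trial)
    ds.validate_complete()
    return ds
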
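"""Rotation algebra: Cardan conversions, joint extraction, mirroring,
gait-cycle normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from reframe_gait import (
    GimbalLockError,
    JointAngleSeries,
    cardan_xyz_to_matrix,
    compute_joint_angles,
    joint_rotation,
    matrix_to_cardan_xyz,
    mirror_left_to_right,
    normalize_gait_cycle,
    to_clinical_display,
)
from reframe_gait.synthetic import (
    MisalignmentSpec,
    SyntheticConfig,
    generate_base_motion,
    observe_through_marker_set,
)

angles_safe = st.floats(-80.0, 80.0)  # away from the beta_y gimbal zone
triplets = st.tuples(st.floats(-179.0, 179.0), angles_safe, st.floats(-179.0, 179.0))


def _single_axis_oracle(alpha, beta, gamma):
    """Explicit single-axis matrices composed by hand (degrees)."""
    a, b, c = np.deg2rad([alpha, beta, gamma])
    rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rz = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
    return rx @ ry @ rz


class TestCardanToMatrix:
    def test_identity(self):
        assert np.allclose(cardan_xyz_to_matrix([0, 0, 0]), np.eye(3), atol=1e-15)

    def test_pure_x_90_maps_y_to_z(self):
        R = cardan_xyz_to_matrix([90, 0, 0])
        expected = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        assert np.allclose(R, expected, atol=1e-15)
        assert np.allclose(R @ np.array([0, 1, 0]), [0, 0, 1], atol=1e-15)

    @given(triplets)
    def test_matches_single_axis_composition(self, trip):
        assert np.allclose(cardan_xyz_to_matrix(trip),
                           _single_axis_oracle(*trip), atol=1e-12)

    def test_matches_scipy_intrinsic_xyz(self, rng):
        ang = rng.uniform(-170, 170, (500, 3))
        ang[:, 1] = rng.uniform(-85, 85, 500)
        ours = cardan_xyz_to_matrix(ang)
        scipy_R = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
        assert np.abs(ours - scipy_R).max() < 1e-12

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            cardan_xyz_to_matrix([np.nan, 0, 0])


class TestMatrixToCardan:
    def test_identity(self):
        assert np.allclose(matrix_to_cardan_xyz(np.eye(3)), [0, 0, 0])

    def test_known_triplet_roundtrip(self):
        trip = np.array([-60.0, 5.0, -8.0])
        back = matrix_to_cardan_xyz(cardan_xyz_to_matrix(trip))
        assert np.abs(back - trip).max() < 1e-9

    @given(triplets)
    @settings(max_examples=300)
    def test_roundtrip_property(self, trip):
        trip = np.asarray(trip)
        back = matrix_to_cardan_xyz(cardan_xyz_to_matrix(trip))
        # alpha/gamma wrap at +/-180; compare via matrices-free modular distance
        diff = (back - trip + 180.0) % 360.0 - 180.0
        assert np.abs(diff).max() < 1e-9

    def test_gimbal_signal_near_90(self):
        R = cardan_xyz_to_matrix([10.0, 89.999999, 0.0])
        with pytest.raises(GimbalLockError) as exc:
            matrix_to_cardan_xyz(R)
        res = exc.value.resolution
        assert res is not None and res[2] == 0.0 and abs(res[1]) == 90.0

    def test_gimbal_resolution_reconstructs_matrix(self):
        R = cardan_xyz_to_matrix([25.0, 90.0, 0.0])
        with pytest.raises(GimbalLockError) as exc:
            matrix_to_cardan_xyz(R)
        R_back = cardan_xyz_to_matrix(exc.value.resolution)
        assert np.abs(R_back - R).max() < 1e-6

    def test_rejects_improper_matrix(self):
        with pytest.raises(ValueError):
            matrix_to_cardan_xyz(np.diag([-1.0, 1.0, 1.0]))


class TestJointRotation:
    def test_equal_frames_give_identity(self, rng):
        R = cardan_xyz_to_matrix(rng.uniform(-60, 60, 3))
        assert np.allclose(joint_rotation(R, R), np.eye(3), atol=1e-12)

    def test_pure_internal_rotation(self):
        Rz10 = cardan_xyz_to_matrix([0, 0, 10])
        J = joint_rotation(np.eye(3), Rz10)
        assert np.allclose(matrix_to_cardan_xyz(J), [0, 0, 10], atol=1e-9)

    def test_matches_basis_projection_oracle(self, rng):
        femur = cardan_xyz_to_matrix(rng.uniform(-60, 60, 3))
        tibia = cardan_xyz_to_matrix(rng.uniform(-60, 60, 3))
        J = joint_rotation(femur, tibia)
        # change of basis: tibial axis vectors expressed in femoral coordinates
        oracle = np.empty((3, 3))
        for j in range(3):
            for i in range(3):
                oracle[i, j] = femur[:, i] @ tibia[:, j]
        assert np.abs(J - oracle).max() < 1e-12

    @given(triplets, triplets, triplets)
    @settings(max_examples=200)
    def test_equivariance_under_common_prerotation(self, f, t, q):
        femur = cardan_xyz_to_matrix(f)
        tibia = cardan_xyz_to_matrix(t)
        Q = cardan_xyz_to_matrix(q)
        J1 = joint_rotation(femur, tibia)
        J2 = joint_rotation(Q @ femur, Q @ tibia)
        assert np.abs(J1 - J2).max() < 1e-9


class TestMirroring:
    def test_pure_flexion_unchanged(self):
        R = cardan_xyz_to_matrix([-60, 0, 0])
        assert np.allclose(mirror_left_to_right(R, kind="poses"), R, atol=1e-12)

    def test_adduction_negated(self):
        femur = np.eye(3)
        tibia = cardan_xyz_to_matrix([0, 5, 0])
        J = joint_rotation(mirror_left_to_right(femur, kind="poses"),
                           mirror_left_to_right(tibia, kind="poses"))
        assert np.allclose(matrix_to_cardan_xyz(J), [0, -5, 0], atol=1e-9)

    @given(triplets)
    @settings(max_examples=200)
    def test_sign_rules_and_involution(self, trip):
        R = cardan_xyz_to_matrix(trip)
        mirrored = mirror_left_to_right(R, kind="poses")
        assert abs(np.linalg.det(mirrored) - 1.0) < 1e-9
        a, b, g = matrix_to_cardan_xyz(mirrored)
        a0, b0, g0 = matrix_to_cardan_xyz(R)
        assert np.allclose([a, b, g], [a0, -b0, -g0], atol=1e-9)
        assert np.abs(mirror_left_to_right(mirrored, kind="poses") - R).max() < 1e-12

    def test_pose_mirror_matches_marker_recipe_oracle(self, rng):
        """M R M equals rebuilding the frame from mirrored markers with a toy
        recipe (anteroposterior and longitudinal axes from point differences,
        mediolateral axis as their cross product)."""

        def recipe(origin, anterior, proximal):
            z = proximal - origin
            z /= np.linalg.norm(z)
            y0 = anterior - origin
            x = np.cross(y0, z)
            x /= np.linalg.norm(x)
            y = np.cross(z, x)
            return np.column_stack([x, y, z])

        for _ in range(50):
            o = rng.normal(size=3)
            ant = o + rng.normal(size=3)
            prox = o + rng.normal(size=3)
            R = recipe(o, ant, prox)
            R_mirrored_markers = recipe(
                mirror_left_to_right(o, kind="points"),
                mirror_left_to_right(ant, kind="points"),
                mirror_left_to_right(prox, kind="points"))
            assert np.abs(
                R_mirrored_markers - mirror_left_to_right(R, kind="poses")
            ).max() < 1e-12

    def test_point_mirroring_negates_x_only(self):
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 5.0, 6.0]])
        out = mirror_left_to_right(pts, kind="points")
        assert np.allclose(out, [[-1, 2, 3], [4, 5, 6]])


class TestComputeJointAngles:
    def test_identical_series_all_zero(self, rng):
        R = cardan_xyz_to_matrix(rng.uniform(-50, 50, (10, 3)))
        series = compute_joint_angles(R, R)
        assert np.abs(series.angles_deg).max() < 1e-9

    def test_constant_flexion_offset(self, rng):
        femur = cardan_xyz_to_matrix(rng.uniform(-40, 40, (20, 3)))
        tibia = femur @ cardan_xyz_to_matrix([-60, 0, 0])
        series = compute_joint_angles(femur, tibia)
        assert np.abs(series.alpha_deg + 60).max() < 1e-9
        disp = to_clinical_display(series)
        assert np.abs(disp[:, 0] - 60).max() < 1e-9

    def test_recovers_generator_truth_without_misalignment(self):
        cfg = SyntheticConfig(n_subjects=1, knees_per_subject=1, trials_per_knee=1,
                              rate_hz=100.0, trial_amp_sd=0.0)
        truth = generate_base_motion(cfg, np.random.default_rng(3))[0]
        femur, tibia = observe_through_marker_set(truth, MisalignmentSpec())
        series = compute_joint_angles(femur, tibia, rate_hz=cfg.rate_hz)
        assert np.abs(series.angles_deg - truth.angles_deg).max() < 1e-9

    def test_length_mismatch_rejected(self):
        R = np.stack([np.eye(3)] * 4)
        with pytest.raises(ValueError, match="mismatch"):
            compute_joint_angles(R, R[:3])

    def test_gimbal_sample_reports_index(self):
        femur = np.stack([np.eye(3)] * 5)
        tibia = femur.copy()
        tibia[3] = cardan_xyz_to_matrix([0, 90, 0])
        with pytest.raises(GimbalLockError) as exc:
            compute_joint_angles(femur, tibia)
        assert exc.value.sample == 3


class TestClinicalDisplay:
    def test_sign_flip_roundtrip(self):
        series = JointAngleSeries.from_degrees(
            np.array([[-60.0, 2.0, -3.0], [0.0, 1.0, 4.0]]))
        disp = to_clinical_display(series)
        assert np.allclose(disp[:, 0], [60.0, 0.0])
        assert np.allclose(disp[:, 1:], series.angles_deg[:, 1:])
        # round trip: flipping the displayed flexion recovers the stored data
        assert np.allclose(disp * np.array([-1.0, 1.0, 1.0]), series.angles_deg)
        # stored data unchanged by the display transform
        assert abs(series.angles_deg[0, 0] + 60.0) < 1e-12


class TestNormalizeGaitCycle:
    def test_constant_signal_stays_constant(self):
        series = JointAngleSeries.from_degrees(np.full((50, 3), 7.0))
        (cycle,) = normalize_gait_cycle(series, [0, 49])
        assert cycle.n_samples == 101
        assert cycle.domain_kind == "percent"
        assert np.abs(cycle.angles_deg - 7.0).max() < 1e-12

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0.0, 10.0, 41)
        series = JointAngleSeries.from_degrees(np.column_stack([ramp] * 3))
        (cycle,) = normalize_gait_cycle(series, [0, 40])
        assert np.abs(cycle.angles_deg[:, 0] - np.linspace(0, 10, 101)).max() < 1e-12

    def test_sinusoid_resample_accuracy(self):
        # 200 Hz sampling of a 1 Hz, 30-deg sinusoid vs the closed form
        t = np.arange(201) / 200.0
        wave = 30.0 * np.sin(2 * np.pi * t)
        series = JointAngleSeries.from_degrees(np.column_stack([wave] * 3))
        (cycle,) = normalize_gait_cycle(series, [0, 200])
        analytic = 30.0 * np.sin(2 * np.pi * cycle.domain / 100.0)
        assert np.abs(cycle.angles_deg[:, 0] - analytic).max() < 0.05

    def test_multiple_cycles_and_monotone_extrema(self):
        t = np.arange(81, dtype=float)
        wave = np.concatenate([np.linspace(0, 50, 41), np.linspace(50, 10, 40)])
        series = JointAngleSeries.from_degrees(np.column_stack([wave] * 3))
        cycles = normalize_gait_cycle(series, [0, 40, 80])
        assert len(cycles) == 2
        assert abs(cycles[0].angles_deg[:, 0].max() - 50.0) < 1e-9
        assert abs(cycles[1].angles_deg[:, 0].min() - 10.0) < 1e-9

    def test_too_few_events_rejected(self):
        series = JointAngleSeries.from_degrees(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            normalize_gait_cycle(series, [0])
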
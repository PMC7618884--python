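import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnmetry.geometry import (
    DegenerateFrameError,
    InsufficientFramesError,
    angular_speed,
    cumulative_angle,
    frame_increment,
    max_angular_velocity,
    pair_vector,
    quantize_to_bin,
)
from turnmetry.skeleton import H36M_JOINT_NAMES, SkeletonSequence

from conftest import body_from_yaw


def _minimal_seq(left_hip, right_hip):
    coords = np.zeros((1, 17, 3))
    J = {n: i for i, n in enumerate(H36M_JOINT_NAMES)}
    coords[0, J["left_hip"]] = left_hip
    coords[0, J["right_hip"]] = right_hip
    return SkeletonSequence(coords=coords, fps=30.0)


class TestPairVector:
    def test_direct_subtraction_drops_vertical(self):
        seq = _minimal_seq([1, 2, 5], [0, 0, 5])
        v = pair_vector(seq, 0, "hip")
        assert (v.vx, v.vy) == (1.0, 2.0)
        assert v.valid

    def test_translation_invariance(self):
        seq = _minimal_seq([1, 2, 5], [0, 0, 5])
        shifted = _minimal_seq([11, 12, 15], [10, 10, 15])
        v, w = pair_vector(seq, 0, "hip"), pair_vector(shifted, 0, "hip")
        assert (v.vx, v.vy) == (w.vx, w.vy)

    def test_coincident_joints_degenerate(self):
        seq = _minimal_seq([1, 1, 5], [1, 1, 5])
        with pytest.raises(DegenerateFrameError):
            pair_vector(seq, 0, "hip")

    def test_masked_frame_falls_back_to_last_valid(self):
        seq = body_from_yaw(np.zeros(3))
        mask = np.ones((3, 17), dtype=bool)
        J = {n: i for i, n in enumerate(H36M_JOINT_NAMES)}
        mask[2, J["left_hip"]] = False
        coords = seq.coords.copy()
        coords[2, J["left_hip"]] = np.nan
        seq2 = SkeletonSequence(coords=coords, fps=50.0, valid_mask=mask)
        v = pair_vector(seq2, 2, "hip")
        assert not v.valid
        ref = pair_vector(seq2, 1, "hip")
        assert (v.vx, v.vy) == (ref.vx, ref.vy)


class TestFrameIncrement:
    def test_orthogonal_vectors(self):
        assert frame_increment((1, 0), (0, 1)) == pytest.approx(90.0)

    def test_parallel_scale_invariant(self):
        assert frame_increment((1, 0), (2, 0)) == pytest.approx(0.0)

    def test_faithful_aliases_above_90(self):
        # arcsin(sin 100 deg) = 80 deg: the unsigned form folds back
        v = (np.cos(np.radians(100)), np.sin(np.radians(100)))
        assert frame_increment((1, 0), v, mode="faithful") == pytest.approx(80.0)
        assert frame_increment((1, 0), v, mode="signed") == pytest.approx(100.0)

    def test_signed_mode_carries_direction(self):
        v = (np.cos(np.radians(-30)), np.sin(np.radians(-30)))
        assert frame_increment((1, 0), v, mode="signed") == pytest.approx(-30.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateFrameError):
            frame_increment((0, 0), (1, 0))

    @given(
        a=st.floats(-180, 180),
        delta=st.floats(-89.9, 89.9),
        s1=st.floats(0.1, 10),
        s2=st.floats(0.1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_faithful_matches_abs_rotation_below_90(self, a, delta, s1, s2):
        u = s1 * np.array([np.cos(np.radians(a)), np.sin(np.radians(a))])
        w = s2 * np.array(
            [np.cos(np.radians(a + delta)), np.sin(np.radians(a + delta))]
        )
        assert frame_increment(u, w, "faithful") == pytest.approx(abs(delta), abs=1e-6)
        assert frame_increment(u, w, "signed") == pytest.approx(delta, abs=1e-6)


class TestCumulativeAngle:
    def test_rigid_rotation_exact(self, rigid_rotation):
        seq = rigid_rotation(step_deg=10.0, n_steps=10)
        est = cumulative_angle(seq, joint_sets=("hip", "knee"))
        assert est.theta_deg == pytest.approx(100.0, abs=1e-6)

    def test_static_skeleton_zero(self, static_body):
        est = cumulative_angle(static_body(), joint_sets=("hip", "knee", "shoulder"))
        assert est.theta_deg == pytest.approx(0.0, abs=1e-9)

    def test_hip_rotating_knee_static_averages(self):
        # hip turns 10 deg/step for 5 steps, knees stay put: average of
        # 10 and 0 per step, summed -> 25
        yaw = 10.0 * np.arange(6)
        seq = body_from_yaw(yaw)
        J = {n: i for i, n in enumerate(H36M_JOINT_NAMES)}
        coords = seq.coords.copy()
        for joint in ("left_knee", "right_knee"):
            coords[:, J[joint]] = coords[0, J[joint]]
        frozen = SkeletonSequence(coords=coords, fps=seq.fps)
        est = cumulative_angle(frozen, joint_sets=("hip", "knee"))
        assert est.theta_deg == pytest.approx(25.0, abs=1e-6)

    def test_accumulator_consistency_and_wmax_bound(self, rigid_rotation):
        seq = rigid_rotation(step_deg=7.0, n_steps=13)
        est = cumulative_angle(seq)
        assert est.theta_deg == pytest.approx(est.increments_deg.sum(), abs=1e-9)
        assert est.wmax_deg_s >= est.omega_deg_s

    def test_too_short_sequence(self):
        seq = SkeletonSequence(coords=np.zeros((1, 17, 3)) + 1, fps=30.0)
        with pytest.raises(InsufficientFramesError):
            cumulative_angle(seq)

    def test_additivity_of_concatenated_clips(self):
        yaw = 6.0 * np.arange(21)
        full = body_from_yaw(yaw)
        a, b = full.slice_frames(0, 11), full.slice_frames(10, 21)
        total = cumulative_angle(full).theta_deg
        assert cumulative_angle(a).theta_deg + cumulative_angle(b).theta_deg == (
            pytest.approx(total, abs=1e-9)
        )

    @pytest.mark.parametrize(
        "transform",
        [
            lambda c: c + np.array([3.0, -7.0, 2.0]),
            lambda c: c * 40.0,
            lambda c: c @ np.array(
                [
                    [np.cos(1.1), np.sin(1.1), 0],
                    [-np.sin(1.1), np.cos(1.1), 0],
                    [0, 0, 1.0],
                ]
            ),
        ],
        ids=["translation", "uniform-scale", "vertical-rotation"],
    )
    def test_similarity_invariance(self, rigid_rotation, transform):
        seq = rigid_rotation(step_deg=8.0, n_steps=12)
        moved = SkeletonSequence(coords=transform(seq.coords), fps=seq.fps)
        for mode in ("faithful", "signed"):
            e0 = cumulative_angle(seq, mode=mode)
            e1 = cumulative_angle(moved, mode=mode)
            assert abs(e1.theta_deg - e0.theta_deg) < 1e-6
            assert abs(e1.omega_deg_s - e0.omega_deg_s) < 1e-6
            assert abs(e1.wmax_deg_s - e0.wmax_deg_s) < 1e-6

    def test_noise_monotonicity_on_static_body(self):
        # unsigned increments can only grow with coordinate noise
        from turnmetry.synthetic import SyntheticTurnSpec, simulate_turn

        means = []
        for sd in (0.005, 0.02):
            thetas = []
            for seed in range(100):
                spec = SyntheticTurnSpec(
                    total_angle_deg=0.0, duration_s=1.0, fps=30.0, noise_sd=sd, seed=seed
                )
                seq, _ = simulate_turn(spec)
                thetas.append(cumulative_angle(seq).theta_deg)
            means.append(np.mean(thetas))
        assert means[1] > means[0] > 0


class TestRates:
    @pytest.mark.parametrize(
        "theta,d,expected", [(180, 2, 90), (0, 5, 0), (45, 1.5, 30)]
    )
    def test_angular_speed(self, theta, d, expected):
        assert angular_speed(theta, d) == pytest.approx(expected)

    def test_angular_speed_bad_duration(self):
        with pytest.raises(ValueError):
            angular_speed(90, 0)

    def test_wmax_is_max_increment_over_dt(self):
        assert max_angular_velocity([1, 3, 2], fps=30) == pytest.approx(90.0)
        assert max_angular_velocity([5.0], fps=1) == pytest.approx(5.0)

    def test_wmax_constant_rate_equals_mean_rate(self):
        inc = [2.0] * 9
        assert max_angular_velocity(inc, fps=10) == pytest.approx(20.0)

    def test_wmax_empty_rejected(self):
        with pytest.raises(InsufficientFramesError):
            max_angular_velocity([], fps=30)


class TestQuantize:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (100.0, 90),  # 90 +/- 22.5 window
            (112.5, 135),  # midpoint rounds half up
            (67.5, 90),
            (45.0, 45),
            (382.4, 360),  # clamps above the top bin
            (0.0, 45),  # clamped to smallest by default
        ],
    )
    def test_bin_assignment(self, theta, expected):
        assert quantize_to_bin(theta) == expected

    def test_sub_threshold_flag_without_clamp(self):
        bins = (45, 90, 135, 180, 225, 270, 315, 360)
        assert quantize_to_bin(20.0, bins, clamp=False) is None
        assert quantize_to_bin(23.0, bins, clamp=False) == 45

    def test_negative_angle_rejected(self):
        with pytest.raises(ValueError):
            quantize_to_bin(-1.0)

    def test_non_multiple_of_45_label_set_rejected(self):
        with pytest.raises(ValueError):
            quantize_to_bin(90.0, label_set=(50, 100))
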
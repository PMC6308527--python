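"""Synthetic generator: closed-form ground truth and sensor synthesis."""

import numpy as np
import pytest

from conftest import noise_free_spec
from vestkin.rotations import axis_angle_rotation, quat_to_matrix
from vestkin.simulate import (
    CONDITIONS,
    SyntheticTrialSpec,
    generate_motion_profile,
    generate_study_specs,
    generate_trial,
    synthesize_imu,
    synthesize_markers,
)


class TestMotionProfile:
    def test_sinusoid_closed_form(self):
        # A = 30 deg, f = 0.5 Hz: ROM = 2A = 60 deg, peak velocity = 2*pi*f*A
        spec = noise_free_spec(head_rom_true=60.0, oscillation_freq=0.5, onset_ramp_cycles=0)
        truth = generate_motion_profile(spec)
        assert truth.half_cycle_rom == pytest.approx(60.0)
        assert truth.peak_velocity == pytest.approx(2 * np.pi * 0.5 * 30.0)
        ser = truth.plane_series("head")
        assert ser.angle.max() == pytest.approx(30.0, abs=1e-6)
        assert ser.velocity.max() == pytest.approx(truth.peak_velocity, rel=1e-9)

    def test_zero_amplitude_is_motionless(self):
        truth = generate_motion_profile(noise_free_spec(head_rom_true=0.0))
        assert np.all(truth.head_euler == 0.0)
        assert np.all(truth.head_rate == 0.0)
        assert truth.turn_intervals == []

    @pytest.mark.parametrize("condition", ["walk_LR", "walk_UD", "tandem_walk_LR"])
    def test_walking_has_path_turns(self, condition):
        truth = generate_motion_profile(noise_free_spec(condition=condition))
        assert len(truth.turn_intervals) >= 2
        for i0, i1 in truth.turn_intervals:
            net = abs(truth.trunk_euler[i1 - 1, 0] - truth.trunk_euler[i0, 0])
            # net heading change of each turn is (close to) 180 degrees
            assert net > 45.0
            peak = np.abs(truth.trunk_rate[i0:i1, 0]).max()
            assert peak > 15.0

    def test_vms_moves_trunk_en_bloc(self):
        truth = generate_motion_profile(noise_free_spec(condition="standing_vms_LR"))
        np.testing.assert_allclose(truth.trunk_euler[:, 0], truth.head_euler[:, 0], atol=1e-12)

    def test_condition_sets_plane(self):
        lr = generate_motion_profile(noise_free_spec(condition="standing_LR"))
        ud = generate_motion_profile(noise_free_spec(condition="standing_UD"))
        assert lr.plane_series("head").plane == "transverse"
        assert ud.plane_series("head").plane == "sagittal"
        # motion goes into yaw for LR, pitch for UD
        assert np.abs(lr.head_euler[:, 0]).max() > 10
        assert np.abs(lr.head_euler[:, 1]).max() < 1e-9
        assert np.abs(ud.head_euler[:, 1]).max() > 10

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTrialSpec(condition="jogging_LR")
        with pytest.raises(ValueError):
            SyntheticTrialSpec(duration=-1)
        with pytest.raises(ValueError):
            SyntheticTrialSpec(oscillation_freq=0)


class TestImuSynthesis:
    def test_static_sensor_reads_gravity_and_field(self):
        spec = noise_free_spec(head_rom_true=0.0)
        head, trunk, _, _ = generate_trial(spec)
        assert np.abs(head.gyro).max() == 0.0
        np.testing.assert_allclose(head.accel, [[0, 0, 9.80665]] * head.n, atol=1e-9)
        np.testing.assert_allclose(head.mag, [[0.2, 0, -0.4]] * head.n, atol=1e-12)

    def test_gyro_matches_analytic_rate_for_pure_yaw(self):
        spec = noise_free_spec(head_rom_true=60.0)
        truth = generate_motion_profile(spec)
        head, _ = synthesize_imu(truth)
        np.testing.assert_allclose(head.gyro[:, 2], truth.head_rate[:, 0], atol=1e-9)

    def test_same_seed_bit_identical(self):
        spec = SyntheticTrialSpec(condition="walk_LR", seed=7)
        a = synthesize_imu(generate_motion_profile(spec))
        b = synthesize_imu(generate_motion_profile(spec))
        for x, y in zip(a, b):
            assert np.array_equal(x.gyro, y.gyro)
            assert np.array_equal(x.accel, y.accel)
            assert np.array_equal(x.mag, y.mag)

    def test_seed_changes_noise_not_truth(self):
        t1 = generate_motion_profile(SyntheticTrialSpec(condition="walk_LR", seed=1))
        t2 = generate_motion_profile(SyntheticTrialSpec(condition="walk_LR", seed=2))
        np.testing.assert_array_equal(t1.head_euler, t2.head_euler)
        g1, _ = synthesize_imu(t1)
        g2, _ = synthesize_imu(t2)
        assert not np.array_equal(g1.gyro, g2.gyro)

    def test_saturation_warns_and_clips(self):
        spec = noise_free_spec(head_rom_true=800.0, oscillation_freq=1.0)  # peak ~2513 deg/s
        truth = generate_motion_profile(spec)
        with pytest.warns(UserWarning, match="saturate"):
            head, _ = synthesize_imu(truth)
        assert np.abs(head.gyro).max() <= 2000.0


class TestMarkerSynthesis:
    def test_static_markers_constant(self):
        spec = noise_free_spec(head_rom_true=0.0)
        markers = synthesize_markers(generate_motion_profile(spec))
        for pos in markers.positions.values():
            np.testing.assert_allclose(pos, np.broadcast_to(pos[0], pos.shape), atol=1e-9)

    def test_mandible_vector_tracks_rotation(self):
        # 90 degrees of true transverse head rotation turns the
        # left->right mandible vector by 90 degrees in the horizontal plane
        spec = noise_free_spec(head_rom_true=180.0, oscillation_freq=0.25, onset_ramp_cycles=0)
        truth = generate_motion_profile(spec)
        markers = synthesize_markers(truth)
        v = markers.positions["r_mandible"] - markers.positions["l_mandible"]
        i0 = 0
        i90 = np.argmin(np.abs(markers.t - (spec.lead_in + 1.0)))  # sin(2*pi*0.25*1) = 1
        cosang = v[i0, :2] @ v[i90, :2] / (np.linalg.norm(v[i0, :2]) * np.linalg.norm(v[i90, :2]))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(90.0, abs=1e-9)

    def test_occlusion_gaps_only_inside_turn_intervals(self):
        spec = SyntheticTrialSpec(condition="walk_LR", occlusion_at_turns=True, seed=3)
        truth = generate_motion_profile(spec)
        markers = synthesize_markers(truth)
        turn_times = [(truth.t[i0], truth.t[i1 - 1]) for i0, i1 in truth.turn_intervals]
        any_gap = False
        for name in markers.positions:
            gaps = markers.gap_mask(name)
            any_gap |= gaps.any()
            for ti in np.flatnonzero(gaps):
                t = markers.t[ti]
                assert any(t0 <= t <= t1 for t0, t1 in turn_times), f"gap outside turns at {t}"
        assert any_gap


class TestTrialBundle:
    def test_duration_includes_lead_in(self):
        head, trunk, markers, truth = generate_trial(noise_free_spec())
        assert head.t[-1] == pytest.approx(33.0, abs=0.02)
        assert markers.t[-1] == pytest.approx(33.0, abs=0.02)
        assert head.nominal_rate == 128.0 and markers.nominal_rate == 120.0

    def test_misalignment_rotates_static_gyro_frame(self):
        mis = quat_to_matrix(axis_angle_rotation([0, 1, 0], 10.0))
        spec = noise_free_spec(head_rom_true=60.0, misalignment=mis)
        truth = generate_motion_profile(spec)
        head, _ = synthesize_imu(truth)
        # yaw rate leaks into the sensor x axis by sin(10 deg)
        ratio = np.abs(head.gyro[:, 0]).max() / np.abs(truth.head_rate[:, 0]).max()
        assert ratio == pytest.approx(np.sin(np.deg2rad(10.0)), rel=1e-6)


class TestStudySpecs:
    def test_study_shape_and_determinism(self):
        specs = generate_study_specs(n_subjects=3, n_trials=2, seed=9)
        assert len(specs) == 3 * 2 * len(CONDITIONS)
        again = generate_study_specs(n_subjects=3, n_trials=2, seed=9)
        assert all(a[2].seed == b[2].seed for a, b in zip(specs, again))

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            generate_study_specs(n_subjects=0)
        with pytest.raises(ValueError):
            generate_study_specs(n_trials=0)
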
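"""IMU arm: sensor fusion, static calibration, plane velocity, integration."""

import numpy as np
import pytest

from conftest import noise_free_spec
from vestkin.imu import (
    CalibrationError,
    estimate_orientation,
    extract_plane_velocity,
    gyro_integration_yaw,
    integrate_displacement,
    static_pose_calibration,
)
from vestkin.rotations import axis_angle_rotation, euler_decompose, quat_to_matrix
from vestkin.simulate import EARTH_FIELD, GRAVITY, SyntheticTrialSpec, generate_trial
from vestkin.streams import ImuStream, PlaneAngleSeries


def yaw_of(quat) -> float:
    return euler_decompose(quat_to_matrix(quat), "ZYX").angle1


def make_stream(t, yaw_deg, yaw_rate_dps):
    """Noise-free level stream rotating about the vertical axis."""
    yaw = np.deg2rad(yaw_deg)
    n = len(t)
    accel = np.zeros((n, 3))
    accel[:, 2] = GRAVITY
    mag = np.stack(
        [
            EARTH_FIELD[0] * np.cos(yaw),
            -EARTH_FIELD[0] * np.sin(yaw),
            np.full(n, EARTH_FIELD[2]),
        ],
        axis=1,
    )
    gyro = np.zeros((n, 3))
    gyro[:, 2] = yaw_rate_dps
    return ImuStream(t=t, accel=accel, gyro=gyro, mag=mag)


class TestOrientationFilter:
    def test_static_stream_stays_at_identity(self, clean_standing_trial):
        spec = noise_free_spec(head_rom_true=0.0, duration=5.0)
        head, *_ = generate_trial(spec)
        orient = estimate_orientation(head).validate()
        angles = np.array(
            [euler_decompose(quat_to_matrix(q)).as_array() for q in orient.quat[::64]]
        )
        assert np.abs(angles).max() < 0.1

    def test_ninety_degree_turn_at_45_dps(self):
        # 2 s static, rotate 90 deg at 45 deg/s, 2 s hold
        t = np.arange(0, 8.0, 1 / 128.0)
        rate = np.where((t >= 2.0) & (t < 4.0), 45.0, 0.0)
        yaw = np.clip((t - 2.0) * 45.0, 0.0, 90.0)
        stream = make_stream(t, yaw, rate)
        orient = estimate_orientation(stream)
        assert yaw_of(orient.quat[-1]) == pytest.approx(90.0, abs=0.5)

    def test_bias_bounded_while_naive_integration_drifts(self):
        spec = noise_free_spec(head_rom_true=0.0, duration=60.0, gyro_bias=0.5, seed=5)
        head, *_ = generate_trial(spec)
        orient = estimate_orientation(head)
        fused_yaw = abs(yaw_of(orient.quat[-1]))
        naive_yaw = abs(gyro_integration_yaw(head)[-1])
        assert fused_yaw < 2.0
        assert naive_yaw > 10 * max(fused_yaw, 0.5)

    def test_free_fall_suspends_gravity_update(self):
        t = np.arange(0, 3.0, 1 / 128.0)
        stream = make_stream(t, np.zeros_like(t), np.zeros_like(t))
        stream.accel[200:300] = 0.0  # free-fall-like dropout
        with pytest.warns(UserWarning, match="gravity correction suspended"):
            estimate_orientation(stream)

    def test_too_short_stream_rejected(self):
        t = np.arange(0, 0.5, 1 / 128.0)
        with pytest.raises(ValueError, match="1 s"):
            estimate_orientation(make_stream(t, np.zeros_like(t), np.zeros_like(t)))


class TestStaticCalibration:
    def test_neutral_mounting_gives_identity(self, clean_standing_trial):
        head, _, _, _, spec = clean_standing_trial
        orient = estimate_orientation(head)
        corr = static_pose_calibration(orient, (0.0, 2.9), stream=head)
        np.testing.assert_allclose(corr, np.eye(3), atol=1e-6)

    def test_recovers_pitch_misalignment_under_noise(self):
        mis = quat_to_matrix(axis_angle_rotation([0, 1, 0], 10.0))
        spec = SyntheticTrialSpec(condition="standing_LR", misalignment=mis, seed=11)
        head, *_ = generate_trial(spec)
        orient = estimate_orientation(head)
        corr = static_pose_calibration(orient, (0.0, 2.9), stream=head)
        pitch = euler_decompose(corr.T, "ZYX").angle2
        assert pitch == pytest.approx(10.0, abs=0.2)

    def test_window_with_motion_rejected(self, clean_standing_trial):
        head, _, _, _, spec = clean_standing_trial
        orient = estimate_orientation(head)
        with pytest.raises(CalibrationError, match="RMS"):
            static_pose_calibration(orient, (4.0, 6.5), stream=head)
        with pytest.raises(CalibrationError, match="RMS"):
            static_pose_calibration(orient, (4.0, 6.5))  # quaternion-derived path

    def test_short_window_rejected(self, clean_standing_trial):
        head, _, _, _, spec = clean_standing_trial
        orient = estimate_orientation(head)
        with pytest.raises(CalibrationError, match="shorter than 1 s"):
            static_pose_calibration(orient, (0.0, 0.5))


class TestPlaneVelocity:
    def test_pure_yaw_projects_to_transverse_only(self, clean_standing_trial):
        head, _, _, truth, spec = clean_standing_trial
        orient = estimate_orientation(head)
        corr = static_pose_calibration(orient, (0.0, 2.9), stream=head)
        vt = extract_plane_velocity(head, orient, corr, "transverse", bias_dps=np.zeros(3))
        vs = extract_plane_velocity(head, orient, corr, "sagittal", bias_dps=np.zeros(3))
        np.testing.assert_allclose(vt.velocity, truth.head_rate[:, 0], atol=0.05)
        assert np.abs(vs.velocity).max() < 0.5

    def test_zero_gyro_gives_zero_velocity(self):
        t = np.arange(0, 2.0, 1 / 128.0)
        stream = make_stream(t, np.zeros_like(t), np.zeros_like(t))
        v = extract_plane_velocity(stream, None, np.eye(3), "transverse")
        assert np.all(v.velocity == 0.0)

    def test_invalid_plane_rejected(self):
        t = np.arange(0, 2.0, 1 / 128.0)
        stream = make_stream(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError, match="plane"):
            extract_plane_velocity(stream, None, np.eye(3), "frontal")

    def test_uncalibrated_mounting_shows_cosine_error(self):
        mis = quat_to_matrix(axis_angle_rotation([0, 1, 0], 10.0))
        spec = noise_free_spec(head_rom_true=60.0, misalignment=mis)
        head, _, _, truth = generate_trial(spec)
        orient = estimate_orientation(head)
        corr = static_pose_calibration(orient, (0.0, 2.9), stream=head)
        calibrated = extract_plane_velocity(head, orient, corr, "transverse", bias_dps=np.zeros(3))
        uncal = extract_plane_velocity(head, orient, np.eye(3), "transverse", bias_dps=np.zeros(3))
        true_peak = np.abs(truth.head_rate[:, 0]).max()
        assert np.abs(calibrated.velocity).max() == pytest.approx(true_peak, rel=0.02)
        assert np.abs(uncal.velocity).max() / true_peak == pytest.approx(
            np.cos(np.deg2rad(10.0)), abs=1e-3
        )

    def test_mounting_equivariance(self, rng):
        # rotating the mounting and supplying the matching correction leaves
        # the projected velocity unchanged
        base = noise_free_spec(head_rom_true=60.0)
        head0, *_ = generate_trial(base)
        mis = quat_to_matrix(axis_angle_rotation(rng.normal(size=3), 25.0))
        head1, *_ = generate_trial(noise_free_spec(head_rom_true=60.0, misalignment=mis))
        v0 = extract_plane_velocity(head0, None, np.eye(3), "transverse")
        v1 = extract_plane_velocity(head1, None, mis.T, "transverse")
        np.testing.assert_allclose(v0.velocity, v1.velocity, atol=1e-9)


class TestIntegrateDisplacement:
    def _series(self, t, vel):
        return PlaneAngleSeries(t=t, plane="transverse", segment="head", velocity=vel)

    def test_constant_velocity_exact(self):
        t = np.arange(0, 2.0 + 1e-9, 1 / 128.0)
        out = integrate_displacement(self._series(t, np.full(len(t), 10.0)))
        assert out.angle[-1] == pytest.approx(20.0, abs=1e-9)

    def test_sinusoid_peak_recovered(self):
        # closed form: angle = A sin(2 pi f t) from velocity 2 pi f A cos(...)
        a_true, f = 30.0, 0.5
        t = np.arange(0, 30.0, 1 / 128.0)
        vel = 2 * np.pi * f * a_true * np.cos(2 * np.pi * f * t)
        out = integrate_displacement(self._series(t, vel))
        assert out.angle.max() == pytest.approx(a_true, abs=0.05)

    def test_zero_velocity_zero_angle(self):
        t = np.arange(0, 2.0, 1 / 128.0)
        out = integrate_displacement(self._series(t, np.zeros(len(t))))
        assert np.all(out.angle == 0.0)

    def test_nonuniform_timestamps_rejected(self):
        t = np.arange(0, 2.0, 1 / 128.0).copy()
        t[50] += 0.003
        with pytest.raises(ValueError, match="uniform"):
            integrate_displacement(self._series(t, np.zeros(len(t))))

    def test_reset_at_zero_crossings_bounds_each_half_cycle(self):
        a_true, f = 30.0, 0.5
        t = np.arange(0, 10.0, 1 / 128.0)
        vel = 2 * np.pi * f * a_true * np.cos(2 * np.pi * f * t)
        out = integrate_displacement(self._series(t, vel), reset_at_zero_crossings=True)
        # each span restarts at zero and sweeps one full ROM = 2A
        assert np.abs(out.angle).max() == pytest.approx(2 * a_true, rel=0.01)
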
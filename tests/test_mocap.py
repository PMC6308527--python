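"""Motion-capture arm: gap fill, filtering, frames, resampling, Euler, rates."""

import numpy as np
import pytest

from conftest import noise_free_spec
from vestkin.mocap import (
    HEAD_SEGMENT,
    TRUNK_SEGMENT,
    build_segment_frames,
    butterworth_dual_pass,
    decompose_segment_angles,
    differentiate_velocity,
    fill_gaps,
    filter_markers,
    resample_series,
)
from vestkin.simulate import generate_motion_profile, synthesize_markers
from vestkin.streams import MarkerStream, PlaneAngleSeries


def simple_markers(n=600, rate=120.0):
    t = np.arange(n) / rate
    pos = {
        "forehead": np.tile([95.0, 0.0, 1725.0], (n, 1)),
        "l_mandible": np.tile([0.0, 60.0, 1650.0], (n, 1)),
        "r_mandible": np.tile([0.0, -60.0, 1650.0], (n, 1)),
        "sternum": np.tile([60.0, 0.0, 1310.0], (n, 1)),
        "l_acromion": np.tile([0.0, 180.0, 1450.0], (n, 1)),
        "r_acromion": np.tile([0.0, -180.0, 1450.0], (n, 1)),
    }
    return MarkerStream(t=t, positions={k: v.copy() for k, v in pos.items()})


class TestFillGaps:
    def test_gap_free_stream_unchanged(self):
        mk = simple_markers()
        out = fill_gaps(mk)
        for name in mk.positions:
            np.testing.assert_array_equal(out.positions[name], mk.positions[name])
        assert out.unfilled == []

    def test_single_sample_on_linear_trajectory(self):
        mk = simple_markers()
        mk.positions["forehead"][:, 0] = 95.0 + 2.0 * mk.t  # linear drift
        expected = mk.positions["forehead"][300].copy()
        mk.positions["forehead"][300] = np.nan
        out = fill_gaps(mk)
        np.testing.assert_allclose(out.positions["forehead"][300], expected, atol=1e-9)

    def test_long_gap_survives_and_reported(self):
        mk = simple_markers()
        mk.positions["sternum"][200:440] = np.nan  # 2 s gap at 120 Hz
        out = fill_gaps(mk, max_gap=0.5)
        assert np.isnan(out.positions["sternum"][300]).all()
        assert any(m == "sternum" for m, _, _ in out.unfilled)


class TestFilterMarkers:
    def test_constant_trajectory_unchanged(self):
        out = filter_markers(simple_markers())
        np.testing.assert_allclose(
            out.positions["forehead"], simple_markers().positions["forehead"], atol=1e-9
        )

    def test_passband_and_stopband(self):
        # dual-pass magnitude is 1/(1+(f/fc)^4): ~0.08% droop at 1 Hz,
        # >99% attenuation at 20 Hz for fc = 6
        t = np.arange(0, 10, 1 / 120.0)
        mk = simple_markers(len(t))
        mk.positions["forehead"][:, 0] += 10.0 * np.sin(2 * np.pi * 1.0 * t)
        mk.positions["forehead"][:, 1] += 10.0 * np.sin(2 * np.pi * 20.0 * t)
        out = filter_markers(mk, cutoff=6.0)
        mid = slice(240, len(t) - 240)
        amp1 = (out.positions["forehead"][mid, 0] - 95.0).max()
        amp20 = np.abs(out.positions["forehead"][mid, 1]).max()
        assert amp1 == pytest.approx(10.0, rel=0.002)
        assert amp20 < 0.01 * 10.0

    def test_short_span_rejected(self):
        mk = simple_markers(n=120)
        mk.positions["forehead"][5:115] = np.nan  # leaves 5-sample spans
        with pytest.raises(ValueError, match="warm-up"):
            filter_markers(mk)


class TestSegmentFrames:
    def test_static_pose_is_identity_after_calibration(self):
        mk = simple_markers()
        frames = build_segment_frames(mk, HEAD_SEGMENT, static_window=(0.0, 2.9))
        np.testing.assert_allclose(
            frames.rotation, np.broadcast_to(np.eye(3), frames.rotation.shape), atol=1e-9
        )

    def test_rigid_rotation_recovered(self):
        spec = noise_free_spec(head_rom_true=180.0, oscillation_freq=0.25, onset_ramp_cycles=0)
        truth = generate_motion_profile(spec)
        mk = synthesize_markers(truth)
        frames = build_segment_frames(mk, HEAD_SEGMENT, static_window=(0.0, 2.9))
        ang = decompose_segment_angles(frames, "transverse")
        i90 = np.argmin(np.abs(mk.t - (spec.lead_in + 1.0)))
        assert ang.angle[i90] == pytest.approx(90.0, abs=1e-6)

    def test_mirrored_markers_rejected(self):
        mk = simple_markers()
        mk.positions["l_mandible"], mk.positions["r_mandible"] = (
            mk.positions["r_mandible"],
            mk.positions["l_mandible"],
        )
        with pytest.raises(ValueError, match="mirrored"):
            build_segment_frames(mk, HEAD_SEGMENT)

    def test_missing_marker_rejected(self):
        mk = simple_markers()
        del mk.positions["forehead"]
        with pytest.raises(ValueError, match="forehead"):
            build_segment_frames(mk, HEAD_SEGMENT)

    def test_translation_invariance(self, rng):
        spec = noise_free_spec(head_rom_true=60.0)
        mk = synthesize_markers(generate_motion_profile(spec))
        shifted = MarkerStream(
            t=mk.t, positions={k: v + np.array([123.0, -45.0, 8.0]) for k, v in mk.positions.items()}
        )
        f0 = build_segment_frames(mk, TRUNK_SEGMENT, static_window=(0.0, 2.9))
        f1 = build_segment_frames(shifted, TRUNK_SEGMENT, static_window=(0.0, 2.9))
        np.testing.assert_allclose(f0.rotation, f1.rotation, atol=1e-9)


class TestResample:
    def _series(self, t, y):
        return PlaneAngleSeries(t=t, plane="transverse", segment="head", angle=y)

    def test_identity_at_same_rate(self):
        t = np.arange(0, 5, 1 / 128.0)
        y = np.sin(t)
        out = resample_series(self._series(t, y), 128.0)
        np.testing.assert_allclose(out.angle, y, atol=1e-12)

    def test_cubic_polynomial_exact(self):
        t = np.arange(0, 5, 1 / 120.0)
        y = 0.5 * t**3 - 2 * t**2 + t - 3
        out = resample_series(self._series(t, y), 128.0)
        expected = 0.5 * out.t**3 - 2 * out.t**2 + out.t - 3
        np.testing.assert_allclose(out.angle, expected, atol=1e-9)

    def test_band_limited_error_small(self):
        t = np.arange(0, 10, 1 / 120.0)
        y = 10.0 * np.sin(2 * np.pi * 3.0 * t)
        out = resample_series(self._series(t, y), 128.0)
        expected = 10.0 * np.sin(2 * np.pi * 3.0 * out.t)
        rms = np.sqrt(np.mean((out.angle - expected) ** 2))
        assert rms < 0.001 * 10.0

    def test_frame_series_resampled_by_slerp(self):
        spec = noise_free_spec(head_rom_true=60.0)
        truth = generate_motion_profile(spec)
        mk = synthesize_markers(truth)
        frames = build_segment_frames(mk, HEAD_SEGMENT, static_window=(0.0, 2.9))
        up = resample_series(frames, 128.0)
        assert up.t[1] - up.t[0] == pytest.approx(1 / 128.0)
        ang = decompose_segment_angles(up, "transverse")
        expected = np.interp(ang.t, truth.t, truth.head_euler[:, 0])
        sel = (ang.t > 4) & (ang.t < 30)
        np.testing.assert_allclose(ang.angle[sel], expected[sel], atol=0.01)


class TestDecomposeAndDifferentiate:
    def test_identity_frames_zero_angle(self):
        frames = build_segment_frames(simple_markers(), HEAD_SEGMENT, static_window=(0.0, 2.9))
        for plane in ("transverse", "sagittal"):
            ang = decompose_segment_angles(frames, plane)
            np.testing.assert_allclose(ang.angle, 0.0, atol=1e-9)

    def test_oscillation_stays_in_its_plane(self):
        spec = noise_free_spec(head_rom_true=80.0, onset_ramp_cycles=0)
        truth = generate_motion_profile(spec)
        frames = build_segment_frames(
            synthesize_markers(truth), HEAD_SEGMENT, static_window=(0.0, 2.9)
        )
        yaw = decompose_segment_angles(frames, "transverse")
        pitch = decompose_segment_angles(frames, "sagittal")
        tp = yaw.t - spec.lead_in
        expected = np.where(tp >= 0, 40.0 * np.sin(2 * np.pi * spec.oscillation_freq * tp), 0.0)
        np.testing.assert_allclose(yaw.angle, expected, atol=1e-6)
        assert np.abs(pitch.angle).max() < 1e-6

    def test_unwrap_across_180(self):
        # continuous rotation through +-180 must not jump
        n = 1200
        t = np.arange(n) / 120.0
        yaw = 60.0 * t  # sweeps through 180 at t = 3 s
        mk = simple_markers(n)
        c, s = np.cos(np.deg2rad(yaw)), np.sin(np.deg2rad(yaw))
        for name in mk.positions:
            p = mk.positions[name].copy()
            x, y = p[:, 0] - 0.0, p[:, 1]
            mk.positions[name][:, 0] = c * x - s * y
            mk.positions[name][:, 1] = s * x + c * y
        frames = build_segment_frames(mk, HEAD_SEGMENT)
        ang = decompose_segment_angles(frames, "transverse")
        assert np.abs(np.diff(ang.angle)).max() < 180.0
        assert ang.angle[-1] - ang.angle[0] == pytest.approx(yaw[-1], abs=1.0)

    def test_differentiate_linear_ramp(self):
        t = np.arange(0, 5, 1 / 128.0)
        ser = PlaneAngleSeries(t=t, plane="transverse", segment="head", angle=10.0 * t)
        out = differentiate_velocity(ser)
        np.testing.assert_allclose(out.velocity[1:-1], 10.0, atol=1e-9)

    def test_differentiate_sinusoid_peak(self):
        a_true, f = 30.0, 0.5
        t = np.arange(0, 30, 1 / 128.0)
        ser = PlaneAngleSeries(
            t=t, plane="transverse", segment="head", angle=a_true * np.sin(2 * np.pi * f * t)
        )
        out = differentiate_velocity(ser)
        assert out.velocity.max() == pytest.approx(2 * np.pi * f * a_true, rel=0.001)

    def test_differentiate_constant_is_zero(self):
        t = np.arange(0, 2, 1 / 128.0)
        ser = PlaneAngleSeries(t=t, plane="transverse", segment="head", angle=np.full(len(t), 5.0))
        np.testing.assert_allclose(differentiate_velocity(ser).velocity, 0.0, atol=1e-12)

    def test_differentiate_too_short_rejected(self):
        ser = PlaneAngleSeries(
            t=np.array([0.0, 0.01]), plane="transverse", segment="head", angle=np.array([0.0, 1.0])
        )
        with pytest.raises(ValueError, match="3 samples"):
            differentiate_velocity(ser)


def test_filter_near_idempotent_on_band_limited_signal():
    # dual-pass droop at f is (f/6)^4 to first order: ~0.4% at 1.5 Hz, so a
    # second application changes a 1.5 Hz signal by less than 0.5%
    t = np.arange(0, 10, 1 / 120.0)
    y = 10.0 * np.sin(2 * np.pi * 1.5 * t)
    once = butterworth_dual_pass(y, 6.0, 120.0)
    twice = butterworth_dual_pass(once, 6.0, 120.0)
    mid = slice(240, len(t) - 240)
    assert np.abs(twice[mid] - once[mid]).max() < 0.005 * 10.0
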
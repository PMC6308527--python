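"""Synthetic paired IMU + optical-marker trials with known ground truth.

The generator emulates the vestibular-rehabilitation task battery: four tasks
(standing, standing with visual-motion-sensitivity "en bloc" movement, walking,
tandem walking), each performed with continuous left/right (transverse-plane)
or up/down (sagittal-plane) head movement on a short walkway.  Every trial
starts with a ~3 s stationary neutral pose used by both measurement arms for
static calibration.

Ground-truth kinematics are closed-form (sinusoidal head oscillation,
raised-cosine 180° path turns at the walkway ends, small gait bounce/sway), so
the quantities the pipelines estimate — per-half-cycle range of motion and
peak angular velocity — are known exactly.  Sensor streams are derived from
the same truth: strap-down gyro/accelerometer/magnetometer signals with bias,
white noise, mounting misalignment and range clipping for the IMUs; rigid-body
marker trajectories with soft-tissue artifact and turn-coincident occlusion
gaps for the optical arm.

All randomness flows from ``SyntheticTrialSpec.seed``; the deterministic
motion profile does not consume random numbers, so two specs differing only in
seed share identical ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .streams import (
    ACCEL_RANGE_MS2,
    GYRO_RANGE_DPS,
    MAG_RANGE_GAUSS,
    ImuStream,
    MarkerStream,
    PlaneAngleSeries,
)

__all__ = [
    "TASKS",
    "DIRECTIONS",
    "CONDITIONS",
    "SyntheticTrialSpec",
    "GroundTruth",
    "generate_motion_profile",
    "synthesize_imu",
    "synthesize_markers",
    "generate_trial",
    "generate_study_specs",
    "random_misalignment",
]

TASKS = ("standing", "standing_vms", "walk", "tandem_walk")
DIRECTIONS = ("LR", "UD")
#: The eight task x direction conditions, in canonical order.
CONDITIONS = tuple(f"{task}_{d}" for task in TASKS for d in DIRECTIONS)

GRAVITY = 9.80665  # m/s^2
#: Earth magnetic field in the world frame (X anterior-at-start, Z up), gauss.
EARTH_FIELD = np.array([0.2, 0.0, -0.4])

IMU_RATE = 128.0
MARKER_RATE = 120.0

# Marker positions in each segment's local frame (X anterior, Y left, Z up), mm.
# The forehead and sternum markers sit off the transverse plane of their
# segment origin, so the raw marker-built anatomical frames are tilted until
# the static-trial correction levels the anterior-posterior axis.
HEAD_MARKER_LOCAL = {
    "r_mandible": np.array([0.0, -60.0, 0.0]),
    "l_mandible": np.array([0.0, 60.0, 0.0]),
    "forehead": np.array([95.0, 0.0, 75.0]),
}
TRUNK_MARKER_LOCAL = {
    "r_acromion": np.array([0.0, -180.0, 0.0]),
    "l_acromion": np.array([0.0, 180.0, 0.0]),
    "sternum": np.array([60.0, 0.0, -140.0]),
}
HEAD_ORIGIN_HEIGHT_MM = 1650.0
TRUNK_ORIGIN_HEIGHT_MM = 1450.0
# IMU mounting points in segment-local coordinates, mm.
HEAD_SENSOR_LOCAL = np.array([90.0, 0.0, 80.0])  # forehead
TRUNK_SENSOR_LOCAL = np.array([60.0, 0.0, -120.0])  # sternum

# Gait plausibility layer: bounce and angular sway at step frequency.
_GAIT = {
    "walk": dict(speed=1.1, step_freq=1.9, bounce_mm=15.0, pitch_sway=1.0, roll_sway=1.5),
    "tandem_walk": dict(speed=0.4, step_freq=1.0, bounce_mm=8.0, pitch_sway=1.0, roll_sway=2.5),
}
TURN_DURATION_S = 2.5
#: Fraction of gait sway transmitted to the head (head stabilisation).
HEAD_SWAY_FACTOR = 0.5


def random_misalignment(rng: np.random.Generator, max_angle_deg: float = 8.0) -> np.ndarray:
    """Random small sensor-mounting rotation (body-from-sensor matrix)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    from .rotations import axis_angle_rotation, quat_to_matrix

    return quat_to_matrix(axis_angle_rotation(axis, angle))


@dataclass
class SyntheticTrialSpec:
    """Parameters of one simulated trial.

    Movement amplitude and frequency are free parameters of the simulator
    (defaults 45° peak-to-peak at 0.5 Hz, a comfortable vestibular-exercise
    pace); they are not measurements of any real cohort.
    """

    condition: str = "standing_LR"
    duration: float = 30.0  # seconds of task, excluding the static lead-in
    lead_in: float = 3.0  # stationary neutral pose for calibration
    head_rom_true: float = 45.0  # degrees, peak-to-peak
    oscillation_freq: float = 0.5  # Hz
    trunk_coupling: Optional[float] = None  # None -> 1.0 for VMS, 0.3 otherwise
    walkway_length: float = 3.9  # metres
    gyro_noise_sd: float = 0.5  # deg/s per sample
    gyro_bias: float = 0.5  # deg/s, magnitude of the constant bias vector
    accel_noise_sd: float = 0.05  # m/s^2 per sample
    mag_noise_sd: float = 0.005  # gauss per sample
    soft_tissue_amp: float = 1.5  # mm, SD of low-frequency marker artifact
    occlusion_at_turns: bool = True
    misalignment: Optional[np.ndarray] = None  # body-from-sensor, both IMUs
    onset_ramp_cycles: float = 1.0  # smooth amplitude ramp-in after the lead-in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.head_rom_true < 0:
            raise ValueError("head_rom_true must be non-negative")
        if self.oscillation_freq <= 0:
            raise ValueError("oscillation_freq must be positive")

    @property
    def task(self) -> str:
        return self.condition.rsplit("_", 1)[0]

    @property
    def direction(self) -> str:
        return self.condition.rsplit("_", 1)[1]

    @property
    def plane(self) -> str:
        return "transverse" if self.direction == "LR" else "sagittal"

    @property
    def is_walking(self) -> bool:
        return self.task in ("walk", "tandem_walk")

    @property
    def coupling(self) -> float:
        if self.trunk_coupling is not None:
            return self.trunk_coupling
        return 1.0 if self.task == "standing_vms" else 0.3

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.duration

    @property
    def amplitude(self) -> float:
        """Oscillation amplitude A in degrees (ROM = 2A)."""
        return 0.5 * self.head_rom_true


def _turn_times(spec: SyntheticTrialSpec) -> List[Tuple[float, float, float]]:
    """(start, end, signed 180° delta) of each locomotor path turn."""
    if not spec.is_walking:
        return []
    gait = _GAIT[spec.task]
    straight = spec.walkway_length / gait["speed"]
    t = spec.lead_in + straight
    out = []
    sign = 1.0
    while t + TURN_DURATION_S <= spec.lead_in + spec.duration:
        out.append((t, t + TURN_DURATION_S, sign * 180.0))
        sign = -sign
        t += TURN_DURATION_S + straight
    return out


def _heading(spec: SyntheticTrialSpec, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form path heading (deg) and heading rate (deg/s)."""
    psi = np.zeros_like(t)
    rate = np.zeros_like(t)
    for start, end, delta in _turn_times(spec):
        u = np.clip((t - start) / (end - start), 0.0, 1.0)
        psi += delta * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        inside = (t >= start) & (t < end)
        rate[inside] += (delta / (end - start)) * (1.0 - np.cos(2 * np.pi * u[inside]))
    return psi, rate


def _oscillation(spec: SyntheticTrialSpec, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Intended head oscillation angle (deg) and rate (deg/s): A sin(2πf t').

    A raised-cosine amplitude envelope over the first ``onset_ramp_cycles``
    cycles avoids an unphysical velocity step at movement onset; with
    ``onset_ramp_cycles = 0`` the series is the literal pure sinusoid.
    """
    tp = t - spec.lead_in
    w = 2 * np.pi * spec.oscillation_freq
    active = tp >= 0
    a = spec.amplitude
    ang = np.where(active, a * np.sin(w * tp), 0.0)
    vel = np.where(active, a * w * np.cos(w * tp), 0.0)
    if spec.onset_ramp_cycles > 0:
        t_ramp = spec.onset_ramp_cycles / spec.oscillation_freq
        ramping = active & (tp < t_ramp)
        u = np.where(ramping, tp / t_ramp, 1.0)
        env = 0.5 * (1.0 - np.cos(np.pi * u))
        denv = np.where(ramping, 0.5 * np.pi / t_ramp * np.sin(np.pi * u), 0.0)
        vel = env * vel + denv * ang
        ang = env * ang
    return ang, vel


def _sway(spec: SyntheticTrialSpec, t: np.ndarray):
    """Gait bounce (mm) and pitch/roll sway (deg) with analytic rates."""
    n = len(t)
    zero = np.zeros(n)
    if not spec.is_walking:
        return zero, zero, zero, zero, zero
    gait = _GAIT[spec.task]
    tp = t - spec.lead_in
    active = tp >= 0
    wstep = 2 * np.pi * gait["step_freq"]
    bounce = np.where(active, gait["bounce_mm"] * np.sin(wstep * tp), 0.0)
    pitch = np.where(active, gait["pitch_sway"] * np.sin(wstep * tp + 0.7), 0.0)
    pitch_rate = np.where(active, gait["pitch_sway"] * wstep * np.cos(wstep * tp + 0.7), 0.0)
    # roll alternates with each step -> stride (half step) frequency
    roll = np.where(active, gait["roll_sway"] * np.sin(0.5 * wstep * tp), 0.0)
    roll_rate = np.where(active, gait["roll_sway"] * 0.5 * wstep * np.cos(0.5 * wstep * tp), 0.0)
    return bounce, pitch, pitch_rate, roll, roll_rate


def _path_position(spec: SyntheticTrialSpec, t: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """Horizontal path position (m), trapezoid-integrated walking velocity."""
    xy = np.zeros((len(t), 2))
    if not spec.is_walking:
        return xy
    gait = _GAIT[spec.task]
    speed = np.where(t >= spec.lead_in, gait["speed"], 0.0)
    # walker slows to a stop at mid-turn, then accelerates out
    for start, end, _ in _turn_times(spec):
        inside = (t >= start) & (t < end)
        u = (t[inside] - start) / (end - start)
        speed[inside] = gait["speed"] * np.cos(np.pi * u) ** 2
    psi = np.deg2rad(psi_deg)
    vel = speed[:, None] * np.stack([np.cos(psi), np.sin(psi)], axis=1)
    dt = np.gradient(t)
    xy[1:] = np.cumsum(0.5 * (vel[1:] + vel[:-1]) * (0.5 * (dt[1:] + dt[:-1]))[:, None], axis=0)
    return xy


def _motion(spec: SyntheticTrialSpec, t: np.ndarray) -> Dict[str, np.ndarray]:
    """Evaluate the full closed-form motion model on an arbitrary time grid.

    Returns intrinsic Z-Y-X Euler angles (yaw, pitch, roll; deg) and their
    rates for both segments, plus the horizontal path position in metres and
    the vertical bounce in millimetres.
    """
    psi, psi_rate = _heading(spec, t)
    osc, osc_rate = _oscillation(spec, t)
    bounce, pitch_sway, pitch_sway_rate, roll_sway, roll_sway_rate = _sway(spec, t)
    c = spec.coupling
    zeros = np.zeros_like(t)

    if spec.direction == "LR":
        head_yaw, head_yaw_rate = psi + osc, psi_rate + osc_rate
        head_pitch, head_pitch_rate = HEAD_SWAY_FACTOR * pitch_sway, HEAD_SWAY_FACTOR * pitch_sway_rate
        trunk_yaw, trunk_yaw_rate = psi + c * osc, psi_rate + c * osc_rate
        trunk_pitch, trunk_pitch_rate = pitch_sway, pitch_sway_rate
    else:  # UD
        head_yaw, head_yaw_rate = psi.copy(), psi_rate.copy()
        head_pitch = osc + HEAD_SWAY_FACTOR * pitch_sway
        head_pitch_rate = osc_rate + HEAD_SWAY_FACTOR * pitch_sway_rate
        trunk_yaw, trunk_yaw_rate = psi.copy(), psi_rate.copy()
        trunk_pitch, trunk_pitch_rate = c * osc + pitch_sway, c * osc_rate + pitch_sway_rate

    head_roll, head_roll_rate = HEAD_SWAY_FACTOR * roll_sway, HEAD_SWAY_FACTOR * roll_sway_rate
    trunk_roll, trunk_roll_rate = roll_sway, roll_sway_rate

    xy = _path_position(spec, t, psi)
    return dict(
        head_euler=np.stack([head_yaw, head_pitch, head_roll], axis=1),
        head_rate=np.stack([head_yaw_rate, head_pitch_rate, head_roll_rate], axis=1),
        trunk_euler=np.stack([trunk_yaw, trunk_pitch, trunk_roll], axis=1),
        trunk_rate=np.stack([trunk_yaw_rate, trunk_pitch_rate, trunk_roll_rate], axis=1),
        path_xy_m=xy,
        bounce_mm=bounce,
        _zeros=zeros,
    )


@dataclass
class GroundTruth:
    """True kinematics of one simulated trial on the 128 Hz IMU grid.

    ``head_euler``/``trunk_euler`` are intrinsic Z-Y-X angles (yaw, pitch,
    roll) in degrees with analytic rates in deg/s.  ``turn_intervals`` are
    half-open sample ranges of the 180° locomotor path turns.  For a pure
    sinusoidal oscillation of amplitude A and frequency f the per-half-cycle
    range of motion is exactly 2A and the peak velocity exactly 2πfA; those
    closed-form values are stored in ``half_cycle_rom`` / ``peak_velocity``.
    """

    spec: SyntheticTrialSpec
    t: np.ndarray
    head_euler: np.ndarray
    head_rate: np.ndarray
    trunk_euler: np.ndarray
    trunk_rate: np.ndarray
    turn_intervals: List[Tuple[int, int]]
    half_cycle_rom: float
    peak_velocity: float

    def plane_series(self, segment: str) -> PlaneAngleSeries:
        """True angle/velocity of ``segment`` in the condition's plane."""
        euler = self.head_euler if segment == "head" else self.trunk_euler
        rate = self.head_rate if segment == "head" else self.trunk_rate
        idx = 0 if self.spec.plane == "transverse" else 1
        return PlaneAngleSeries(
            t=self.t,
            plane=self.spec.plane,
            segment=segment,
            angle=euler[:, idx].copy(),
            velocity=rate[:, idx].copy(),
        )

    def trunk_heading_series(self) -> PlaneAngleSeries:
        """True trunk transverse series (the locomotor-turn detection signal)."""
        return PlaneAngleSeries(
            t=self.t,
            plane="transverse",
            segment="trunk",
            angle=self.trunk_euler[:, 0].copy(),
            velocity=self.trunk_rate[:, 0].copy(),
        )

    def turn_sample_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.t), dtype=bool)
        for i0, i1 in self.turn_intervals:
            mask[i0:i1] = True
        return mask


def generate_motion_profile(spec: SyntheticTrialSpec) -> GroundTruth:
    """Evaluate the deterministic motion model on the 128 Hz grid."""
    n = int(round(spec.total_duration * IMU_RATE))
    t = np.arange(n) / IMU_RATE
    m = _motion(spec, t)
    intervals = []
    for start, end, _ in _turn_times(spec):
        i0 = int(np.searchsorted(t, start, side="left"))
        i1 = int(np.searchsorted(t, end, side="left"))
        intervals.append((i0, i1))
    w = 2 * np.pi * spec.oscillation_freq
    return GroundTruth(
        spec=spec,
        t=t,
        head_euler=m["head_euler"],
        head_rate=m["head_rate"],
        trunk_euler=m["trunk_euler"],
        trunk_rate=m["trunk_rate"],
        turn_intervals=intervals,
        half_cycle_rom=spec.head_rom_true,
        peak_velocity=spec.amplitude * w,
    )


def _euler_rates_to_body_omega(euler_deg: np.ndarray, rates_dps: np.ndarray) -> np.ndarray:
    """Exact body-frame angular velocity (deg/s) from Z-Y-X Euler angles/rates."""
    yaw, pitch, roll = np.deg2rad(euler_deg).T
    dyaw, dpitch, droll = rates_dps.T  # keep deg/s; transform is linear
    sp, cp = np.sin(pitch), np.cos(pitch)
    sr, cr = np.sin(roll), np.cos(roll)
    wx = droll - dyaw * sp
    wy = dpitch * cr + dyaw * cp * sr
    wz = dyaw * cp * cr - dpitch * sr
    return np.stack([wx, wy, wz], axis=1)


def _world_from_body(euler_deg: np.ndarray) -> np.ndarray:
    """Stack of world-from-body rotation matrices from Z-Y-X Euler angles."""
    yaw, pitch, roll = np.deg2rad(euler_deg).T
    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    r = np.empty((len(yaw), 3, 3))
    r[:, 0, 0] = cy * cp
    r[:, 0, 1] = cy * sp * sr - sy * cr
    r[:, 0, 2] = cy * sp * cr + sy * sr
    r[:, 1, 0] = sy * cp
    r[:, 1, 1] = sy * sp * sr + cy * cr
    r[:, 1, 2] = sy * sp * cr - cy * sr
    r[:, 2, 0] = -sp
    r[:, 2, 1] = cp * sr
    r[:, 2, 2] = cp * cr
    return r


def _segment_origin_mm(m: Dict[str, np.ndarray], segment: str) -> np.ndarray:
    height = HEAD_ORIGIN_HEIGHT_MM if segment == "head" else TRUNK_ORIGIN_HEIGHT_MM
    n = len(m["bounce_mm"])
    origin = np.zeros((n, 3))
    origin[:, :2] = m["path_xy_m"] * 1000.0
    origin[:, 2] = height + m["bounce_mm"]
    return origin


def synthesize_imu(
    truth: GroundTruth, spec: Optional[SyntheticTrialSpec] = None
) -> Tuple[ImuStream, ImuStream]:
    """Strap-down IMU signals (head, trunk) derived from the ground truth.

    gyro = misaligned body angular velocity + constant bias + white noise;
    accel = specific force (gravity + linear acceleration of the mounting
    point) in the sensor frame + noise; mag = Earth field in the sensor frame
    + noise.  All channels are clipped to the advertised sensor ranges and a
    warning is raised if the true angular velocity saturates the gyro.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng([spec.seed, 1])
    mis = np.eye(3) if spec.misalignment is None else np.asarray(spec.misalignment)
    t = truth.t
    dt = 1.0 / IMU_RATE
    m = _motion(spec, t)
    streams = []
    for segment, euler, rate, sensor_local in (
        ("head", truth.head_euler, truth.head_rate, HEAD_SENSOR_LOCAL),
        ("trunk", truth.trunk_euler, truth.trunk_rate, TRUNK_SENSOR_LOCAL),
    ):
        r_wb = _world_from_body(euler)
        omega_b = _euler_rates_to_body_omega(euler, rate)
        if np.any(np.abs(omega_b) > GYRO_RANGE_DPS):
            warnings.warn(
                f"{segment} angular velocity exceeds the ±{GYRO_RANGE_DPS:g} °/s "
                "gyro range; signal will saturate",
                stacklevel=2,
            )
        # sensor world position in metres for linear acceleration
        origin = _segment_origin_mm(m, segment)
        pos_m = (origin + np.einsum("nij,j->ni", r_wb, sensor_local)) / 1000.0
        vel = np.gradient(pos_m, dt, axis=0)
        acc_w = np.gradient(vel, dt, axis=0)
        specific_force_w = acc_w + np.array([0.0, 0.0, GRAVITY])
        r_ws = r_wb @ mis  # world-from-sensor
        gyro_s = omega_b @ mis  # row-wise M^T @ omega
        bias_axis = rng.normal(size=3)
        bias_axis /= np.linalg.norm(bias_axis)
        bias = spec.gyro_bias * bias_axis
        gyro = gyro_s + bias + spec.gyro_noise_sd * rng.standard_normal(gyro_s.shape)
        accel = np.einsum("nji,nj->ni", r_ws, specific_force_w)
        accel = accel + spec.accel_noise_sd * rng.standard_normal(accel.shape)
        mag = np.einsum("nji,j->ni", r_ws, EARTH_FIELD)
        mag = mag + spec.mag_noise_sd * rng.standard_normal(mag.shape)
        streams.append(
            ImuStream(
                t=t.copy(),
                accel=np.clip(accel, -ACCEL_RANGE_MS2, ACCEL_RANGE_MS2),
                gyro=np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS),
                mag=np.clip(mag, -MAG_RANGE_GAUSS, MAG_RANGE_GAUSS),
                nominal_rate=IMU_RATE,
                site=segment,
            )
        )
    return streams[0], streams[1]


def _soft_tissue(rng: np.random.Generator, n: int, sd_mm: float, rate: float) -> np.ndarray:
    """Low-frequency (≲1.5 Hz) marker artifact with the requested SD."""
    white = rng.normal(size=(n, 3))
    if sd_mm <= 0:
        return np.zeros((n, 3))
    from scipy.signal import butter, filtfilt

    b, a = butter(2, 1.5 / (rate / 2.0))
    low = filtfilt(b, a, white, axis=0)
    low *= sd_mm / np.std(low, axis=0, keepdims=True)
    return low


def synthesize_markers(
    truth: GroundTruth, spec: Optional[SyntheticTrialSpec] = None
) -> MarkerStream:
    """Six-marker optical stream at 120 Hz from the rigid-body ground truth."""
    spec = spec or truth.spec
    rng = np.random.default_rng([spec.seed, 2])
    n = int(round(spec.total_duration * MARKER_RATE))
    t = np.arange(n) / MARKER_RATE
    m = _motion(spec, t)
    positions: Dict[str, np.ndarray] = {}
    for segment, locals_ in (("head", HEAD_MARKER_LOCAL), ("trunk", TRUNK_MARKER_LOCAL)):
        euler = m[f"{segment}_euler"]
        r_wb = _world_from_body(euler)
        origin = _segment_origin_mm(m, segment)
        for name, local in locals_.items():
            pos = origin + np.einsum("nij,j->ni", r_wb, local)
            pos = pos + _soft_tissue(rng, n, spec.soft_tissue_amp, MARKER_RATE)
            positions[name] = pos
    if spec.occlusion_at_turns and spec.is_walking:
        occluded = ("forehead", "r_mandible", "sternum")
        for start, end, _ in _turn_times(spec):
            mid = 0.5 * (start + end)
            sel = (t >= mid - 0.175) & (t <= mid + 0.175)  # 0.35 s dropout
            for name in occluded:
                positions[name][sel] = np.nan
    return MarkerStream(t=t, positions=positions, nominal_rate=MARKER_RATE)


def generate_trial(
    spec: SyntheticTrialSpec,
) -> Tuple[ImuStream, ImuStream, MarkerStream, GroundTruth]:
    """Bundle ground truth, both IMU streams, and the marker stream."""
    truth = generate_motion_profile(spec)
    imu_head, imu_trunk = synthesize_imu(truth, spec)
    markers = synthesize_markers(truth, spec)
    return imu_head, imu_trunk, markers, truth


def generate_study_specs(
    n_subjects: int = 10,
    n_trials: int = 2,
    seed: int = 0,
    conditions=CONDITIONS,
    noise_free: bool = False,
) -> List[Tuple[str, int, SyntheticTrialSpec]]:
    """Specs for a full validation study: subjects x trials x conditions.

    Per-subject movement amplitude (30-60° peak-to-peak) and pace
    (0.4-0.8 Hz) are drawn once per subject; each trial adds a small
    amplitude jitter and its own sensor-noise seed.  Mounting misalignment is
    drawn per subject (sensors are donned once).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng([seed, 77])
    out = []
    for s in range(n_subjects):
        rom = rng.uniform(30.0, 60.0)
        freq = rng.uniform(0.4, 0.8)
        mis = random_misalignment(rng, max_angle_deg=8.0)
        for cond in conditions:
            for k in range(n_trials):
                jitter = rng.uniform(0.95, 1.05)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                kwargs = dict(
                    condition=cond,
                    head_rom_true=rom * jitter,
                    oscillation_freq=freq,
                    misalignment=mis,
                    seed=trial_seed,
                )
                if noise_free:
                    kwargs.update(
                        gyro_noise_sd=0.0,
                        gyro_bias=0.0,
                        accel_noise_sd=0.0,
                        mag_noise_sd=0.0,
                        soft_tissue_amp=0.0,
                        occlusion_at_turns=False,
                        misalignment=None,
                    )
                out.append((f"S{s:02d}", k, SyntheticTrialSpec(**kwargs)))
    return out
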
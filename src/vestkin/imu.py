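"""IMU measurement arm: sensor fusion, static calibration, plane kinematics.

Orientation is estimated with a multiplicative error-state Kalman filter
(MEKF) on the unit quaternion, with gyroscope bias in the state: the gyro
propagates attitude, the accelerometer corrects tilt whenever the specific
force is close to 1 g, and the magnetometer corrects heading only (a scalar
yaw update, so magnetic disturbance cannot corrupt tilt).

A static neutral pose at the start of each recording calibrates the constant
sensor-to-segment mounting rotation; angular velocity is then projected onto
the anatomical plane of interest (vertical axis for transverse left/right
motion, mediolateral axis for sagittal up/down motion) and integrated to
angular displacement.  Peak-velocity metrics downstream read the projected
gyro signal directly rather than differentiating displacement, since the gyro
is the direct measurement of rotational velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .rotations import matrix_to_quat, quat_multiply, quat_to_matrix
from .streams import ImuStream, OrientationSeries, PlaneAngleSeries

__all__ = [
    "FusionParams",
    "CalibrationError",
    "estimate_orientation",
    "static_pose_calibration",
    "extract_plane_velocity",
    "integrate_displacement",
    "gyro_integration_yaw",
]

GRAVITY = 9.80665


class CalibrationError(RuntimeError):
    """Raised when the static window is unusable for calibration."""


@dataclass
class FusionParams:
    """Tuning constants of the orientation filter.

    Defaults were calibrated once against the synthetic generator's default
    noise model and are deliberately conservative: the accelerometer
    direction noise is inflated well above the sensor noise floor so that
    linear accelerations during walking do not drag the tilt estimate.
    """

    gyro_noise_dps: float = 0.5  # white noise driving attitude, deg/s
    gyro_bias_rw_dps: float = 0.02  # bias random walk, deg/s per sqrt(s)
    accel_dir_noise: float = 0.06  # gravity-direction noise, rad
    mag_heading_noise: float = 0.05  # heading measurement noise, rad
    accel_gate: float = 0.10  # accept accel update when ||a|| within 10% of 1 g
    accel_gyro_gate_dps: float = 15.0  # ...and rotation slower than this
    init_window_s: float = 0.5  # samples averaged for the initial attitude
    p0_att_deg: float = 5.0
    p0_bias_dps: float = 1.0


def _qmul_rotvec(qw, qx, qy, qz, px, py, pz):
    """Scalar Hamilton product q ⊗ exp([px,py,pz]/2), renormalised."""
    import math

    angle = math.sqrt(px * px + py * py + pz * pz)
    if angle < 1e-12:
        dw, dx, dy, dz = 1.0, 0.5 * px, 0.5 * py, 0.5 * pz
    else:
        half = 0.5 * angle
        s = math.sin(half) / angle
        dw, dx, dy, dz = math.cos(half), s * px, s * py, s * pz
    w = qw * dw - qx * dx - qy * dy - qz * dz
    x = qw * dx + qx * dw + qy * dz - qz * dy
    y = qw * dy - qx * dz + qy * dw + qz * dx
    z = qw * dz + qx * dy - qy * dx + qz * dw
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return w / n, x / n, y / n, z / n


def _inv3(S: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a 3x3 matrix (adjugate / determinant)."""
    a, b, c = S[0]
    d, e, f = S[1]
    g, h, i = S[2]
    A = e * i - f * h
    B = c * h - b * i
    C = b * f - c * e
    D = f * g - d * i
    E = a * i - c * g
    F = c * d - a * f
    G = d * h - e * g
    H = b * g - a * h
    I = a * e - b * d
    det = a * A + b * D + c * G
    return np.array([[A, B, C], [D, E, F], [G, H, I]]) / det


def _triad_init(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """World-from-sensor matrix from averaged accel (up) and mag (north)."""
    up = accel / np.linalg.norm(accel)
    m_h = mag - np.dot(mag, up) * up
    nh = np.linalg.norm(m_h)
    if nh < 1e-12:
        north = np.array([1.0, 0.0, 0.0])  # heading unobservable; pick arbitrary
    else:
        north = m_h / nh
    west = np.cross(up, north)
    return np.stack([north, west, up], axis=0)


def estimate_orientation(
    stream: ImuStream, params: Optional[FusionParams] = None
) -> OrientationSeries:
    """Per-sample world-from-sensor orientation by accel/gyro/mag fusion.

    Requires at least one second of data.  If the accelerometer reads near
    zero (free-fall-like), the gravity correction is suspended for those
    samples and a warning is emitted.
    """
    params = params or FusionParams()
    stream.validate()
    t = stream.t
    n = len(t)
    if t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of data for orientation estimation")
    dt = stream.dt
    gyro = np.deg2rad(stream.gyro)
    accel = stream.accel
    mag = stream.mag

    n_init = max(2, int(round(params.init_window_s / dt)))
    q = matrix_to_quat(_triad_init(accel[:n_init].mean(axis=0), mag[:n_init].mean(axis=0)))
    b = np.zeros(3)  # gyro bias, rad/s

    p_att = np.deg2rad(params.p0_att_deg) ** 2
    p_bias = np.deg2rad(params.p0_bias_dps) ** 2
    P = np.diag([p_att] * 3 + [p_bias] * 3)
    q_att = (np.deg2rad(params.gyro_noise_dps)) ** 2 * dt
    q_bias = (np.deg2rad(params.gyro_bias_rw_dps)) ** 2 * dt
    Q = np.diag([q_att] * 3 + [q_bias] * 3)
    r_acc = params.accel_dir_noise**2
    r_mag = params.mag_heading_noise**2
    gate_lo = GRAVITY * (1.0 - params.accel_gate)
    gate_hi = GRAVITY * (1.0 + params.accel_gate)
    gyro_gate = np.deg2rad(params.accel_gyro_gate_dps)

    quats = np.empty((n, 4))
    biases = np.empty((n, 3))
    F = np.eye(6)
    F[0:3, 3:6] = -dt * np.eye(3)
    free_fall = 0
    qw, qx, qy, qz = q
    bx, by, bz = b
    import math

    atan2 = math.atan2
    eye3_racc = r_acc * np.eye(3)

    for i in range(n):
        if i > 0:
            # midpoint (trapezoidal) gyro keeps integration second-order
            gm = 0.5 * (gyro[i - 1] + gyro[i])
            wx, wy, wz = gm[0] - bx, gm[1] - by, gm[2] - bz
            pxr, pyr, pzr = wx * dt, wy * dt, wz * dt
            qw, qx, qy, qz = _qmul_rotvec(qw, qx, qy, qz, pxr, pyr, pzr)
            F[0, 1] = pzr
            F[0, 2] = -pyr
            F[1, 0] = -pzr
            F[1, 2] = pxr
            F[2, 0] = pyr
            F[2, 1] = -pxr
            P = F @ P @ F.T + Q

        # third row of R(q) = world up expressed in the sensor frame
        ux = 2.0 * (qx * qz - qw * qy)
        uy = 2.0 * (qy * qz + qw * qx)
        uz = 1.0 - 2.0 * (qx * qx + qy * qy)

        a = accel[i]
        anorm = math.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])
        gi = gyro[i]
        spin = math.sqrt(gi[0] * gi[0] + gi[1] * gi[1] + gi[2] * gi[2])
        if anorm < 0.5:
            free_fall += 1
        elif gate_lo <= anorm <= gate_hi and spin <= gyro_gate:
            y = np.array([a[0] / anorm - ux, a[1] / anorm - uy, a[2] / anorm - uz])
            Hs = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
            PHt = P[:, 0:3] @ Hs.T  # H = [skew(u), 0]
            S = Hs @ PHt[0:3] + eye3_racc
            K = PHt @ _inv3(S)
            delta = K @ y
            qw, qx, qy, qz = _qmul_rotvec(qw, qx, qy, qz, delta[0], delta[1], delta[2])
            bx += delta[3]
            by += delta[4]
            bz += delta[5]
            P = P - K @ PHt.T
            ux = 2.0 * (qx * qz - qw * qy)
            uy = 2.0 * (qy * qz + qw * qx)
            uz = 1.0 - 2.0 * (qx * qx + qy * qy)

        # heading innovation from the horizontal magnetometer component
        m = mag[i]
        # world-frame field: rows of R dotted with m; need x,y components
        mwx = (1.0 - 2.0 * (qy * qy + qz * qz)) * m[0] + 2.0 * (qx * qy - qw * qz) * m[1] + 2.0 * (
            qx * qz + qw * qy
        ) * m[2]
        mwy = 2.0 * (qx * qy + qw * qz) * m[0] + (1.0 - 2.0 * (qx * qx + qz * qz)) * m[1] + 2.0 * (
            qy * qz - qw * qx
        ) * m[2]
        if mwx * mwx + mwy * mwy > 1e-12:
            gamma = atan2(mwy, mwx)  # reference horizontal field is +X
            u = np.array([ux, uy, uz])
            PHt = P[:, 0:3] @ u  # H = [u^T, 0]
            S = u @ PHt[0:3] + r_mag
            K = PHt / S
            delta = K * (-gamma)
            qw, qx, qy, qz = _qmul_rotvec(qw, qx, qy, qz, delta[0], delta[1], delta[2])
            bx += delta[3]
            by += delta[4]
            bz += delta[5]
            P = P - np.outer(K, PHt)

        quats[i, 0] = qw
        quats[i, 1] = qx
        quats[i, 2] = qy
        quats[i, 3] = qz
        biases[i, 0] = bx
        biases[i, 1] = by
        biases[i, 2] = bz

    if free_fall:
        warnings.warn(
            f"accelerometer near zero on {free_fall} samples; gravity correction suspended",
            stacklevel=2,
        )
    # hemisphere continuity
    flips = np.cumsum(np.sum(quats[1:] * quats[:-1], axis=1) < 0) % 2
    quats[1:][flips == 1] *= -1.0
    if quats[0, 0] < 0:
        quats *= -1.0
    return OrientationSeries(t=t.copy(), quat=quats, gyro_bias=np.rad2deg(biases))


def gyro_integration_yaw(stream: ImuStream) -> np.ndarray:
    """Naive yaw by direct trapezoidal integration of the raw z gyro (deg).

    Reference for drift comparisons; no bias or fusion correction.
    """
    from scipy.integrate import cumulative_trapezoid

    return np.concatenate([[0.0], cumulative_trapezoid(stream.gyro[:, 2], stream.t)])


def _mean_quaternion(quats: np.ndarray) -> np.ndarray:
    """Markley's eigenvector average of unit quaternions."""
    a = quats.T @ quats
    vals, vecs = np.linalg.eigh(a)
    q = vecs[:, -1]
    return q if q[0] >= 0 else -q


def static_pose_calibration(
    orient: OrientationSeries,
    static_window: Tuple[float, float],
    max_gyro_rms_dps: float = 3.0,
    stream: Optional[ImuStream] = None,
) -> np.ndarray:
    """Sensor-to-segment correction from a stationary neutral pose.

    Returns the rotation ``C`` such that right-multiplying the estimated
    world-from-sensor orientation expresses the anatomical segment in the
    world frame, with the neutral pose mapping to identity (anterior axis
    horizontal, vertical axis up).  The window must be at least 1 s long and
    quiet: angular velocity RMS (derived from the quaternion increments) must
    stay below ``max_gyro_rms_dps``.
    """
    t0, t1 = static_window
    if t1 - t0 < 1.0:
        raise CalibrationError(f"static window {t1 - t0:.2f} s is shorter than 1 s")
    sel = (orient.t >= t0) & (orient.t <= t1)
    if sel.sum() < 3:
        raise CalibrationError("static window contains fewer than 3 samples")
    q = orient.quat[sel]
    if stream is not None:
        gsel = (stream.t >= t0) & (stream.t <= t1)
        dev = stream.gyro[gsel] - stream.gyro[gsel].mean(axis=0)
        rms = float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
    else:
        # body-frame angular increments; smooth before the motion check so
        # per-sample estimator jitter is not mistaken for movement
        from .rotations import quat_conjugate

        dt = np.diff(orient.t[sel])
        dq = quat_multiply(quat_conjugate(q[:-1]), q[1:])
        rates = np.rad2deg(2.0 * dq[:, 1:] / dt[:, None])
        k = max(1, int(round(0.1 / np.median(dt))))
        kernel = np.ones(k) / k
        sm = np.column_stack([np.convolve(rates[:, j], kernel, mode="same") for j in range(3)])
        sm -= sm.mean(axis=0)
        rms = float(np.sqrt(np.mean(np.sum(sm**2, axis=1))))
    if rms > max_gyro_rms_dps:
        raise CalibrationError(
            f"motion in static window: angular-velocity RMS {rms:.1f} °/s "
            f"exceeds {max_gyro_rms_dps:g} °/s"
        )
    r_mean = quat_to_matrix(_mean_quaternion(q))
    return r_mean.T


def extract_plane_velocity(
    stream: ImuStream,
    orient: Optional[OrientationSeries],
    correction: np.ndarray,
    plane: str,
    segment: str = "head",
    bias_dps: Optional[np.ndarray] = None,
) -> PlaneAngleSeries:
    """Anatomical-plane angular velocity from the calibrated gyro signal.

    The gyro vector is bias-corrected (``bias_dps`` if given — typically the
    mean gyro reading over the static pose — otherwise the fusion filter's
    per-sample bias estimate), rotated into the anatomical frame, and
    projected on the plane's normal: the vertical axis for the transverse
    plane, the mediolateral axis for the sagittal plane.
    """
    if plane not in ("transverse", "sagittal"):
        raise ValueError(f"plane must be 'transverse' or 'sagittal', got {plane!r}")
    correction = np.asarray(correction, dtype=float)
    gyro = stream.gyro
    if bias_dps is not None:
        gyro = gyro - np.asarray(bias_dps, dtype=float)
    elif orient is not None and orient.gyro_bias is not None:
        gyro = gyro - orient.gyro_bias
    omega_body = gyro @ correction  # row-wise C^T @ omega_sensor
    component = omega_body[:, 2] if plane == "transverse" else omega_body[:, 1]
    return PlaneAngleSeries(
        t=stream.t.copy(), plane=plane, segment=segment, velocity=component.copy()
    )


def integrate_displacement(
    series: PlaneAngleSeries, reset_at_zero_crossings: bool = False
) -> PlaneAngleSeries:
    """Angular displacement by trapezoidal integration of plane velocity.

    With ``reset_at_zero_crossings`` the running integral restarts at every
    velocity zero-crossing, so each half-cycle's excursion is measured from
    its own start and integration drift cannot accumulate across turns.  The
    default keeps a single running integral (turn metrics difference the
    angle across each turn, which bounds drift to one half-cycle anyway).
    """
    from scipy.integrate import cumulative_trapezoid

    if series.velocity is None:
        raise ValueError("velocity must be populated before integration")
    dt = np.diff(series.t)
    if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt):
        raise ValueError("timestamps deviate more than 1% from uniform sampling")
    angle = np.concatenate([[0.0], cumulative_trapezoid(series.velocity, series.t)])
    if reset_at_zero_crossings:
        v = series.velocity
        crossings = np.flatnonzero(np.signbit(v[:-1]) != np.signbit(v[1:])) + 1
        for idx in crossings:
            angle[idx:] -= angle[idx]
    return PlaneAngleSeries(
        t=series.t.copy(),
        plane=series.plane,
        segment=series.segment,
        angle=angle,
        velocity=series.velocity.copy(),
    )
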
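"""3-D rotation machinery shared by the IMU and motion-capture pipelines.

Conventions (fixed package-wide, enforced by tests):

* Quaternions are scalar-first ``(w, x, y, z)`` and unit-norm, and represent
  world-from-sensor (or world-from-segment) rotations: ``v_world = R(q) v_body``.
* The anatomical segment frame is right-handed with X anterior,
  Y to the subject's left, Z up.
* Euler decomposition is intrinsic Z-Y-X: angle1 = axial rotation about the
  vertical axis (transverse plane, positive = leftward turn), angle2 = flexion
  about the mediolateral axis (sagittal plane, positive = downward tilt of the
  anterior axis), angle3 = lateral bending.  This puts the two planes that
  vestibular head-turn tasks exercise (transverse for left/right, sagittal for
  up/down) in the first two slots, which minimises cross-talk between them.
* Angles are degrees at every public boundary; radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerAngles",
    "axis_angle_rotation",
    "compose_rotations",
    "quat_conjugate",
    "quat_multiply",
    "quat_normalize",
    "quat_rotate",
    "quat_to_matrix",
    "matrix_to_quat",
    "euler_decompose",
    "euler_compose",
    "align_frame",
    "is_rotation_matrix",
    "GIMBAL_LOCK_DEG",
]

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])

#: |angle2| at or beyond which the Z-Y-X decomposition is degenerate.
GIMBAL_LOCK_DEG = 89.999


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic Euler angles in degrees for a given axis sequence.

    ``gimbal_lock`` is set when ``|angle2|`` reaches the degenerate zone; in
    that case only the sum/difference of angle1 and angle3 is observable and
    angle3 is conventionally reported as 0.
    """

    angle1: float
    angle2: float
    angle3: float
    sequence: str = "ZYX"
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.angle1, self.angle2, self.angle3])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Renormalise a quaternion (or array of them) to unit length."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm quaternion cannot be normalised")
    return q / norm


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` (apply q first, then p), scalar-first."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = np.moveaxis(p, -1, 0)
    qw, qx, qy, qz = np.moveaxis(q, -1, 0)
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q``: body -> world."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def axis_angle_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit quaternion for a right-hand-rule rotation of ``angle_deg`` about ``axis``.

    The axis is normalised internally; a zero-norm axis is rejected.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-15:
        raise ValueError("rotation axis must have nonzero norm")
    half = 0.5 * np.deg2rad(angle_deg)
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = np.sin(half) * (axis / norm)
    return q


def compose_rotations(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Rotation equivalent to applying ``first`` then ``second``.

    Because quaternions act on the left (``v' = R(q) v``), the composite is
    ``second ⊗ first``.  The result is renormalised to absorb round-off.
    """
    return quat_normalize(quat_multiply(second, first))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Direction-cosine matrix (world-from-body) for scalar-first quaternion(s)."""
    q = quat_normalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def matrix_to_quat(matrix: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion from a proper rotation matrix (Shepperd's method)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError("expected a 3x3 rotation matrix")
    single = m.ndim == 2
    m = m.reshape(-1, 3, 3)
    q = np.empty((m.shape[0], 4))
    tr = np.einsum("nii->n", m)
    for i, (mi, t) in enumerate(zip(m, tr)):
        if t > 0:
            s = np.sqrt(t + 1.0) * 2.0
            q[i] = [0.25 * s, (mi[2, 1] - mi[1, 2]) / s, (mi[0, 2] - mi[2, 0]) / s, (mi[1, 0] - mi[0, 1]) / s]
        elif mi[0, 0] >= mi[1, 1] and mi[0, 0] >= mi[2, 2]:
            s = np.sqrt(1.0 + mi[0, 0] - mi[1, 1] - mi[2, 2]) * 2.0
            q[i] = [(mi[2, 1] - mi[1, 2]) / s, 0.25 * s, (mi[0, 1] + mi[1, 0]) / s, (mi[0, 2] + mi[2, 0]) / s]
        elif mi[1, 1] >= mi[2, 2]:
            s = np.sqrt(1.0 - mi[0, 0] + mi[1, 1] - mi[2, 2]) * 2.0
            q[i] = [(mi[0, 2] - mi[2, 0]) / s, (mi[0, 1] + mi[1, 0]) / s, 0.25 * s, (mi[1, 2] + mi[2, 1]) / s]
        else:
            s = np.sqrt(1.0 - mi[0, 0] - mi[1, 1] + mi[2, 2]) * 2.0
            q[i] = [(mi[1, 0] - mi[0, 1]) / s, (mi[0, 2] + mi[2, 0]) / s, (mi[1, 2] + mi[2, 1]) / s, 0.25 * s]
    q = quat_normalize(q)
    # canonical hemisphere: non-negative scalar part
    q[q[:, 0] < 0] *= -1.0
    return q[0] if single else q


def is_rotation_matrix(matrix: np.ndarray, tol: float = 1e-6) -> bool:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    return (
        np.allclose(m.T @ m, np.eye(3), atol=tol)
        and abs(np.linalg.det(m) - 1.0) < tol
    )


_AXES = {"X": 0, "Y": 1, "Z": 2}


def _single_axis_matrix(axis: str, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == "X":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "Y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "Z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def euler_compose(angles_deg, sequence: str = "ZYX") -> np.ndarray:
    """Rotation matrix from intrinsic Euler angles (degrees) in ``sequence`` order."""
    seq = sequence.upper()
    if len(seq) != 3 or any(a not in _AXES for a in seq):
        raise ValueError(f"invalid Euler sequence {sequence!r}")
    r = np.eye(3)
    for axis, angle in zip(seq, np.deg2rad(np.asarray(angles_deg, dtype=float))):
        # intrinsic: successive rotations about the rotated axes => right-multiply
        r = r @ _single_axis_matrix(axis, angle)
    return r


def euler_decompose(rotation: np.ndarray, sequence: str = "ZYX") -> EulerAngles:
    """Intrinsic Euler decomposition of a rotation matrix, angles in degrees.

    Only Tait-Bryan sequences (three distinct axes) are supported; the package
    uses Z-Y-X throughout.  Near gimbal lock (|angle2| >= ``GIMBAL_LOCK_DEG``)
    the result is flagged and angle3 is set to 0.
    """
    seq = sequence.upper()
    if len(seq) != 3 or len(set(seq)) != 3 or any(a not in _AXES for a in seq):
        raise ValueError(f"unsupported Euler sequence {sequence!r} (need three distinct axes)")
    m = np.asarray(rotation, dtype=float)
    if not is_rotation_matrix(m, tol=1e-6):
        raise ValueError("input is not a proper rotation matrix")
    i, j, k = (_AXES[a] for a in seq)
    # permutation parity: +1 for cyclic axis order (XYZ, YZX, ZXY), -1 otherwise
    eps = 1.0 if (i, j, k) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else -1.0
    # Intrinsic i-j-k, R = R_i(a1) R_j(a2) R_k(a3):
    #   m[i,k] = eps*sin(a2);  a1 from column k;  a3 from row i.
    s2 = np.clip(eps * m[i, k], -1.0, 1.0)
    angle2 = np.arcsin(s2)
    if np.abs(np.rad2deg(angle2)) >= GIMBAL_LOCK_DEG:
        # a3 unobservable; fold everything into a1 (sign of the fold depends
        # on which pole of a2 we are at)
        angle3 = 0.0
        angle1 = np.sign(eps * s2) * np.arctan2(eps * m[j, i], m[j, j])
        return EulerAngles(
            float(np.rad2deg(angle1)), float(np.rad2deg(angle2)), angle3, seq, gimbal_lock=True
        )
    angle1 = np.arctan2(-eps * m[j, k], m[k, k])
    angle3 = np.arctan2(-eps * m[i, j], m[i, i])
    return EulerAngles(
        float(np.rad2deg(angle1)),
        float(np.rad2deg(angle2)),
        float(np.rad2deg(angle3)),
        seq,
        gimbal_lock=False,
    )


def align_frame(orientation: np.ndarray, correction: np.ndarray) -> np.ndarray:
    """Re-express a world-from-sensor orientation in the anatomical frame.

    ``correction`` is the sensor-from-anatomical rotation obtained from a
    static calibration trial, so the aligned orientation is
    ``R_world_from_body = R_world_from_sensor @ correction`` (right-multiply).
    """
    correction = np.asarray(correction, dtype=float)
    if not is_rotation_matrix(correction, tol=1e-6):
        raise ValueError("correction is not a proper rotation matrix")
    qc = matrix_to_quat(correction)
    return quat_normalize(quat_multiply(orientation, qc))
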
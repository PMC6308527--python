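"""Optical motion-capture criterion arm.

Processing chain: cubic-spline gap filling, zero-phase low-pass filtering of
marker trajectories (dual-pass 2nd-order Butterworth, 6 Hz default),
anatomical segment frames from the six-marker set, up-sampling to the IMU
rate, intrinsic Z-Y-X Euler decomposition, and central-difference
differentiation of the plane angle to rotational velocity.

Segment frames follow the clinical convention: the mediolateral axis is taken
exactly (origin toward the right-side landmark), the anterior-posterior axis
is the anterior landmark direction orthogonalised against it, and the
vertical axis completes the right-handed triad.  A static neutral window
levels the anterior-posterior axis (the forehead and sternum landmarks sit
above/below their segment origins, so raw marker frames are tilted); all
angles are therefore measured relative to the calibrated neutral pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .rotations import matrix_to_quat, quat_to_matrix
from .streams import MarkerStream, PlaneAngleSeries

__all__ = [
    "SegmentDefinition",
    "SegmentFrameSeries",
    "HEAD_SEGMENT",
    "TRUNK_SEGMENT",
    "fill_gaps",
    "filter_markers",
    "build_segment_frames",
    "resample_series",
    "decompose_segment_angles",
    "differentiate_velocity",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentDefinition:
    """Marker recipe for one anatomical segment frame.

    The origin is the midpoint of ``origin_markers``; the mediolateral axis
    points from the origin to ``right_marker``; the anterior-posterior axis
    points from the origin to ``anterior_marker`` (orthogonalised against the
    mediolateral axis); the vertical axis is orthogonal to both, completing a
    right-handed set.
    """

    name: str
    origin_markers: Tuple[str, str]
    right_marker: str
    anterior_marker: str

    @property
    def markers(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys([*self.origin_markers, self.right_marker, self.anterior_marker]))


HEAD_SEGMENT = SegmentDefinition(
    name="head",
    origin_markers=("r_mandible", "l_mandible"),
    right_marker="r_mandible",
    anterior_marker="forehead",
)
TRUNK_SEGMENT = SegmentDefinition(
    name="trunk",
    origin_markers=("r_acromion", "l_acromion"),
    right_marker="r_acromion",
    anterior_marker="sternum",
)


@dataclass
class SegmentFrameSeries:
    """Per-sample world-from-segment rotations and origin trajectory (mm)."""

    t: np.ndarray
    rotation: np.ndarray  # (n, 3, 3)
    origin: np.ndarray  # (n, 3) mm
    valid: np.ndarray  # (n,) bool, False where markers missing or degenerate
    segment: str = ""


def _nan_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def fill_gaps(stream: MarkerStream, max_gap: float = 0.5) -> MarkerStream:
    """Cubic-spline fill of marker dropouts up to ``max_gap`` seconds.

    Longer gaps are left missing and reported in the returned stream's
    ``unfilled`` list as ``(marker, t_start, t_end)``.
    """
    dt = float(np.median(np.diff(stream.t)))
    out: Dict[str, np.ndarray] = {}
    unfilled: List[Tuple[str, float, float]] = []
    for name, pos in stream.positions.items():
        pos = pos.copy()
        missing = np.isnan(pos).any(axis=1)
        if missing.any():
            valid = ~missing
            if valid.sum() >= 4:
                spline = CubicSpline(stream.t[valid], pos[valid], axis=0)
                for start, stop in _nan_runs(missing):
                    gap_len = (stop - start) * dt
                    interior = start > 0 and stop < len(stream.t)
                    if gap_len <= max_gap and interior:
                        pos[start:stop] = spline(stream.t[start:stop])
                    else:
                        unfilled.append((name, float(stream.t[start]), float(stream.t[stop - 1])))
            else:
                for start, stop in _nan_runs(missing):
                    unfilled.append((name, float(stream.t[start]), float(stream.t[stop - 1])))
        out[name] = pos
    for name, t0, t1 in unfilled:
        log.warning("unfillable gap in marker %s: %.3f-%.3f s", name, t0, t1)
    return MarkerStream(
        t=stream.t.copy(), positions=out, nominal_rate=stream.nominal_rate, unfilled=unfilled
    )


def butterworth_dual_pass(x: np.ndarray, cutoff: float, rate: float, order: int = 2) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth low-pass along axis 0."""
    b, a = butter(order, cutoff / (rate / 2.0))
    return filtfilt(b, a, x, axis=0)


def filter_markers(stream: MarkerStream, cutoff: float = 6.0) -> MarkerStream:
    """Dual-pass 2nd-order Butterworth low-pass of every marker coordinate.

    Each gap-free span is filtered separately; a span too short for the
    filter's edge padding is an error.
    """
    b, a = butter(2, cutoff / (stream.nominal_rate / 2.0))
    padlen = 3 * max(len(a), len(b))
    out: Dict[str, np.ndarray] = {}
    for name, pos in stream.positions.items():
        pos = pos.copy()
        missing = np.isnan(pos).any(axis=1)
        for start, stop in _nan_runs(~missing):
            if stop - start <= padlen:
                raise ValueError(
                    f"marker {name!r}: span of {stop - start} samples is too short "
                    f"for the filter warm-up ({padlen} samples)"
                )
            pos[start:stop] = filtfilt(b, a, pos[start:stop], axis=0)
        out[name] = pos
    return MarkerStream(
        t=stream.t.copy(),
        positions=out,
        nominal_rate=stream.nominal_rate,
        unfilled=list(stream.unfilled),
    )


def _mean_rotation(rotations: np.ndarray) -> np.ndarray:
    quats = matrix_to_quat(rotations)
    a = quats.T @ quats
    _, vecs = np.linalg.eigh(a)
    return quat_to_matrix(vecs[:, -1])


def build_segment_frames(
    stream: MarkerStream,
    definition: SegmentDefinition,
    static_window: Optional[Tuple[float, float]] = None,
) -> SegmentFrameSeries:
    """Anatomical frame series for one segment from its marker recipe.

    With ``static_window`` the mean orientation over that (gap-free, quiet)
    window becomes the neutral reference: returned rotations are
    neutral-from-current, identity in the static pose.  Samples with missing
    or collinear markers are flagged invalid.  A left-handed triad in the
    static pose (vertical axis pointing down, i.e. left/right marker labels
    swapped) is rejected.
    """
    for m in definition.markers:
        if m not in stream.positions:
            raise ValueError(f"marker {m!r} required by segment {definition.name!r} is absent")
    p_o1 = stream.positions[definition.origin_markers[0]]
    p_o2 = stream.positions[definition.origin_markers[1]]
    p_r = stream.positions[definition.right_marker]
    p_a = stream.positions[definition.anterior_marker]
    origin = 0.5 * (p_o1 + p_o2)
    ml = p_r - origin
    ap = p_a - origin

    n = len(stream.t)
    valid = ~(np.isnan(ml).any(axis=1) | np.isnan(ap).any(axis=1))
    rot = np.full((n, 3, 3), np.nan)
    ml_n = np.linalg.norm(ml, axis=1)
    ok = valid & (ml_n > 1e-9)
    r_hat = np.zeros_like(ml)
    r_hat[ok] = ml[ok] / ml_n[ok, None]
    ap_perp = ap - np.sum(ap * r_hat, axis=1, keepdims=True) * r_hat
    ap_n = np.linalg.norm(ap_perp, axis=1)
    ok &= ap_n > 1e-9
    a_hat = np.zeros_like(ap_perp)
    a_hat[ok] = ap_perp[ok] / ap_n[ok, None]
    v_hat = np.cross(r_hat, a_hat)
    # body axes in world: X anterior, Y left (= -right), Z up
    rot[ok, :, 0] = a_hat[ok]
    rot[ok, :, 1] = -r_hat[ok]
    rot[ok, :, 2] = v_hat[ok]
    valid = ok

    if not valid.any():
        raise ValueError(f"segment {definition.name!r}: no sample has a complete marker set")
    first = int(np.flatnonzero(valid)[0])
    if rot[first, 2, 2] <= 0:
        raise ValueError(
            f"segment {definition.name!r}: vertical axis points downward — "
            "left/right markers appear mirrored (handedness check failed)"
        )

    if static_window is not None:
        t0, t1 = static_window
        sel = valid & (stream.t >= t0) & (stream.t <= t1)
        if sel.sum() < 2:
            raise ValueError("static window contains fewer than 2 valid samples")
        # the marker-built triad differs from the true segment frame by a
        # constant local rotation (landmarks off the origin's transverse
        # plane tilt the raw AP axis); the static pose identifies it, and a
        # right-side correction removes it: R(t) <- R_raw(t) R_static^T
        r_ref = _mean_rotation(rot[sel])
        rot[valid] = np.einsum("nij,kj->nik", rot[valid], r_ref)
    return SegmentFrameSeries(
        t=stream.t.copy(), rotation=rot, origin=origin, valid=valid, segment=definition.name
    )


def resample_series(series, target_rate: float = 128.0):
    """Resample a uniformly sampled series onto a ``target_rate`` grid.

    Scalar series (``PlaneAngleSeries``) are cubic-spline interpolated;
    rotation series (``SegmentFrameSeries``) use quaternion slerp for the
    rotations and a cubic spline for the origin.  The target grid spans the
    overlap of the source range only.
    """
    t = series.t
    t_new = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * target_rate)) + 1) / target_rate
    if t_new[0] < t[0] - 1e-9 or t_new[-1] > t[-1] + 1e-9:
        raise ValueError("target grid extends outside the source time range")
    if isinstance(series, PlaneAngleSeries):
        out = PlaneAngleSeries(t=t_new, plane=series.plane, segment=series.segment)
        for attr in ("angle", "velocity"):
            arr = getattr(series, attr)
            if arr is not None:
                setattr(out, attr, CubicSpline(t, arr)(t_new))
        return out
    if isinstance(series, SegmentFrameSeries):
        if not series.valid.all():
            raise ValueError("cannot resample a frame series with invalid samples; fill gaps first")
        from scipy.spatial.transform import Rotation, Slerp

        rot = Rotation.from_matrix(series.rotation)
        slerp = Slerp(t, rot)
        return SegmentFrameSeries(
            t=t_new,
            rotation=slerp(t_new).as_matrix(),
            origin=CubicSpline(t, series.origin, axis=0)(t_new),
            valid=np.ones(len(t_new), dtype=bool),
            segment=series.segment,
        )
    raise TypeError(f"cannot resample object of type {type(series).__name__}")


def decompose_segment_angles(frames: SegmentFrameSeries, plane: str) -> PlaneAngleSeries:
    """Plane angle (degrees, unwrapped) from the frame series.

    Transverse = first (yaw) angle of the intrinsic Z-Y-X decomposition,
    sagittal = second (flexion) angle.  Invalid samples propagate as NaN.
    """
    if plane not in ("transverse", "sagittal"):
        raise ValueError(f"plane must be 'transverse' or 'sagittal', got {plane!r}")
    r = frames.rotation
    angle = np.full(len(frames.t), np.nan)
    v = frames.valid
    if plane == "transverse":
        angle[v] = np.rad2deg(np.arctan2(r[v, 1, 0], r[v, 0, 0]))
    else:
        # pitch = -asin(R[2,0]); positive flexion tips the anterior axis down
        angle[v] = np.rad2deg(-np.arcsin(np.clip(r[v, 2, 0], -1.0, 1.0)))
    if v.all():
        angle = np.unwrap(angle, period=360.0)
    else:
        angle[v] = np.unwrap(angle[v], period=360.0)
    return PlaneAngleSeries(t=frames.t.copy(), plane=plane, segment=frames.segment, angle=angle)


def differentiate_velocity(series: PlaneAngleSeries) -> PlaneAngleSeries:
    """Rotational velocity by central differences (one-sided at the ends)."""
    if series.angle is None:
        raise ValueError("angle must be populated before differentiation")
    if len(series.t) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vel = np.gradient(series.angle, series.t)
    return PlaneAngleSeries(
        t=series.t.copy(),
        plane=series.plane,
        segment=series.segment,
        angle=series.angle.copy(),
        velocity=vel,
    )
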
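"""Shared time-series containers for the IMU and motion-capture arms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

#: Marker names required by the head/trunk segment model.
REQUIRED_MARKERS = (
    "forehead",
    "l_mandible",
    "r_mandible",
    "sternum",
    "l_acromion",
    "r_acromion",
)

GYRO_RANGE_DPS = 2000.0
ACCEL_RANGE_MS2 = 6.0 * 9.80665
MAG_RANGE_GAUSS = 6.0

PLANES = ("transverse", "sagittal")
SEGMENTS = ("head", "trunk")


def _check_uniform(t: np.ndarray, nominal_rate: float, tol: float = 0.01) -> None:
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two timestamps")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    rate = 1.0 / np.median(dt)
    if abs(rate - nominal_rate) > tol * nominal_rate:
        raise ValueError(
            f"observed rate {rate:.2f} Hz deviates more than {tol:.0%} "
            f"from nominal {nominal_rate:g} Hz"
        )


@dataclass
class ImuStream:
    """Raw samples from one body-worn inertial unit.

    accel in m/s^2, gyro in deg/s, mag in gauss; rows are samples at
    ``nominal_rate`` (128 Hz for the devices this package models).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    nominal_rate: float = 128.0
    site: str = ""  # "head" (forehead) or "trunk" (sternum)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("accel", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.t), 3):
                raise ValueError(f"{name} must have shape (n, 3) matching timestamps")
            setattr(self, name, arr)

    def validate(self) -> "ImuStream":
        _check_uniform(self.t, self.nominal_rate)
        if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS + 1e-9):
            raise ValueError(f"gyro magnitudes exceed the ±{GYRO_RANGE_DPS:g} °/s sensor range")
        return self

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class MarkerStream:
    """Named 3-D marker trajectories in millimetres, NaN marking gaps."""

    t: np.ndarray
    positions: Dict[str, np.ndarray]
    nominal_rate: float = 120.0
    unfilled: List[Tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = {
            k: np.asarray(v, dtype=float) for k, v in self.positions.items()
        }
        for k, v in self.positions.items():
            if v.shape != (len(self.t), 3):
                raise ValueError(f"marker {k!r} must have shape (n, 3)")

    def validate(self, required=REQUIRED_MARKERS) -> "MarkerStream":
        _check_uniform(self.t, self.nominal_rate, tol=0.05)
        missing = [m for m in required if m not in self.positions]
        if missing:
            raise ValueError(
                f"missing required markers {missing}; required set is {list(required)}"
            )
        return self

    def gap_mask(self, marker: str) -> np.ndarray:
        """Boolean mask, True where the marker is missing."""
        return np.isnan(self.positions[marker]).any(axis=1)

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass
class OrientationSeries:
    """Per-sample world-from-sensor unit quaternions (scalar-first)."""

    t: np.ndarray
    quat: np.ndarray
    gyro_bias: Optional[np.ndarray] = None  # deg/s, per-sample filter estimate

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.quat.shape != (len(self.t), 4):
            raise ValueError("quat must have shape (n, 4)")

    def validate(self) -> "OrientationSeries":
        norms = np.linalg.norm(self.quat, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("orientation quaternions must be unit-norm")
        dots = np.sum(self.quat[1:] * self.quat[:-1], axis=1)
        if np.any(dots < 0):
            raise ValueError("quaternion sign flips: successive samples not in same hemisphere")
        return self


@dataclass
class PlaneAngleSeries:
    """Scalar angle (+ angular velocity) of one segment in one anatomical plane.

    ``plane`` is ``"transverse"`` (left/right, yaw about the vertical axis) or
    ``"sagittal"`` (up/down, pitch about the mediolateral axis); angle in
    degrees, velocity in deg/s.
    """

    t: np.ndarray
    plane: str
    segment: str
    angle: Optional[np.ndarray] = None
    velocity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        self.t = np.asarray(self.t, dtype=float)
        for name in ("angle", "velocity"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.t.shape:
                    raise ValueError(f"{name} must match timestamps in length")
                setattr(self, name, arr)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))
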
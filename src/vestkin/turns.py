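"""Head-turn segmentation, locomotor-turn exclusion, and per-trial metrics.

A continuous head-movement trial is segmented into individual head turns at
zero-crossings of the (lightly smoothed) plane angular velocity: each span
between successive velocity reversals is one half-cycle excursion.  A turn's
range of motion (ROM) is the absolute angle change across the span and its
peak velocity the maximum absolute angular velocity within it.  Small
incidental movements are rejected by minimum-ROM and minimum-peak-velocity
gates.

During walking trials the 180° direction changes at the ends of the walkway
would masquerade as huge head turns; they are detected on the trunk
transverse (heading) series by the classic double threshold — net turn angle
greater than 45° and peak turn velocity greater than 15 °/s — and excluded,
with a guard band on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .mocap import butterworth_dual_pass
from .streams import PlaneAngleSeries

__all__ = [
    "HeadTurn",
    "TurnExclusionMask",
    "TrialMetrics",
    "detect_locomotor_turns",
    "segment_head_turns",
    "summarize_trial",
    "TURN_ANGLE_THRESHOLD_DEG",
    "TURN_VELOCITY_THRESHOLD_DPS",
]

log = logging.getLogger(__name__)

#: Locomotor-turn double threshold: net angle and peak velocity.
TURN_ANGLE_THRESHOLD_DEG = 45.0
TURN_VELOCITY_THRESHOLD_DPS = 15.0


@dataclass(frozen=True)
class HeadTurn:
    """One segmented head excursion (half-cycle between velocity reversals)."""

    start: int
    end: int
    direction: int
    rom: float  # degrees, absolute excursion
    peak_velocity: float  # deg/s, max |velocity| within the turn

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("turn start must precede end")
        if self.rom < 0 or self.peak_velocity < 0:
            raise ValueError("rom and peak_velocity must be non-negative")


@dataclass
class TurnExclusionMask:
    """Per-sample exclusion of locomotor path turns."""

    mask: np.ndarray  # bool per sample, True = excluded
    intervals: List[Tuple[int, int]] = field(default_factory=list)
    notice: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @classmethod
    def empty(cls, n: int, notice: str = "") -> "TurnExclusionMask":
        return cls(mask=np.zeros(n, dtype=bool), intervals=[], notice=notice)


@dataclass(frozen=True)
class TrialMetrics:
    """Average ROM and average peak rotational velocity of one trial."""

    condition: str
    segment: str
    device: str  # "imu", "mocap", or "truth"
    avg_rom: float
    avg_peak_velocity: float
    n_turns: int


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_locomotor_turns(
    yaw_series: PlaneAngleSeries,
    is_walking: bool = True,
    angle_threshold: float = TURN_ANGLE_THRESHOLD_DEG,
    velocity_threshold: float = TURN_VELOCITY_THRESHOLD_DPS,
    guard_s: float = 0.25,
    candidate_floor_dps: float = 10.0,
    merge_gap_s: float = 0.25,
    heading_cutoff_hz: float = 0.3,
) -> TurnExclusionMask:
    """Flag 180° walking-path turns on the trunk heading series.

    The continuous left/right head-and-trunk oscillation overlaps the path
    turns in frequency, so turns are detected on the heading trend: the
    unwrapped yaw angle is zero-phase low-passed at ``heading_cutoff_hz``
    (which averages out the zero-mean oscillation but keeps the 180° steps)
    and intervals of sustained trend slope above ``candidate_floor_dps`` are
    flagged when the net angle change exceeds ``angle_threshold`` AND the
    peak raw velocity within them exceeds ``velocity_threshold``.  The
    exclusion mask covers flagged intervals plus a ``guard_s`` band on each
    side.  Applied to a standing condition the mask is empty by construction.
    """
    n = len(yaw_series.t)
    if not is_walking:
        notice = "standing condition: no locomotor turns to exclude"
        log.info(notice)
        return TurnExclusionMask.empty(n, notice)
    if yaw_series.angle is None or yaw_series.velocity is None:
        raise ValueError("yaw series must have angle and velocity populated")
    rate = yaw_series.rate
    trend = butterworth_dual_pass(yaw_series.angle, heading_cutoff_hz, rate)
    v_trend = np.gradient(trend, yaw_series.t)
    cand = np.abs(v_trend) > candidate_floor_dps
    gap = int(round(merge_gap_s * rate))
    runs = _runs(cand)
    merged: List[Tuple[int, int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    guard = int(round(guard_s * rate))
    mask = np.zeros(n, dtype=bool)
    intervals: List[Tuple[int, int]] = []
    for i0, i1 in merged:
        net = abs(trend[i1 - 1] - trend[i0])
        peak = np.abs(yaw_series.velocity[i0:i1]).max()
        if net > angle_threshold and peak > velocity_threshold:
            j0, j1 = max(0, i0 - guard), min(n, i1 + guard)
            mask[j0:j1] = True
            intervals.append((j0, j1))
    return TurnExclusionMask(mask=mask, intervals=intervals)


def segment_head_turns(
    series: PlaneAngleSeries,
    mask: Optional[TurnExclusionMask] = None,
    min_rom: float = 5.0,
    min_peak: float = 10.0,
    crossing_cutoff_hz: float = 2.0,
    hysteresis_dps: float = 1.0,
) -> List[HeadTurn]:
    """Individual head turns between velocity zero-crossings.

    The velocity is low-passed at ``crossing_cutoff_hz`` (zero-phase) for
    crossing detection only; ROM and peak velocity are read from the
    unsmoothed series.  A zero-crossing counts as a movement reversal only
    if the smoothed velocity reaches ``hysteresis_dps`` on both sides, so
    numerical wobble around zero (quiet stance, filter edge effects) cannot
    fragment the series.  Leading/trailing partial spans (not bounded by
    reversals on both sides) are dropped, as are turns overlapping the
    exclusion mask, turns with ROM below ``min_rom``, turns with peak
    velocity below ``min_peak``, and spans containing missing samples.
    """
    if series.angle is None or series.velocity is None:
        raise ValueError("series must have angle and velocity populated")
    n = len(series.t)
    if n < 3:
        raise ValueError("series too short to segment")
    finite = np.isfinite(series.velocity)
    v_for_crossings = np.where(finite, series.velocity, 0.0)
    v_smooth = butterworth_dual_pass(v_for_crossings, crossing_cutoff_hz, series.rate)
    crossings = np.flatnonzero(np.diff(np.signbit(v_smooth).astype(int)) != 0) + 1
    # spans between crossings, including the partial lead and tail
    bounds = np.concatenate([[0], crossings, [n]])
    strong: List[Tuple[int, int, int]] = []  # (start, end, sign)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        seg = v_smooth[a:b]
        peak_idx = int(np.argmax(np.abs(seg)))
        if abs(seg[peak_idx]) >= hysteresis_dps:
            strong.append((int(a), int(b), 1 if seg[peak_idx] > 0 else -1))
    # merge consecutive same-sign strong spans (the weak wobble between them
    # is not a true reversal)
    merged: List[Tuple[int, int, int]] = []
    for span in strong:
        if merged and merged[-1][2] == span[2]:
            merged[-1] = (merged[-1][0], span[1], span[2])
        else:
            merged.append(span)
    # reversal boundaries sit where the sign actually flips; the first and
    # last merged spans are partial (not bounded by reversals on both sides)
    turns: List[HeadTurn] = []
    boundaries = [span[0] for span in merged[1:]]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b - a < 2:
            continue
        if mask is not None and mask.mask[a:b].any():
            continue
        seg_angle = series.angle[a:b]
        seg_vel = series.velocity[a:b]
        if not (np.isfinite(seg_angle).all() and np.isfinite(seg_vel).all()):
            continue
        rom = abs(float(series.angle[b - 1] - series.angle[a]))
        peak = float(np.abs(seg_vel).max())
        if rom < min_rom or peak < min_peak:
            continue
        direction = int(np.sign(series.angle[b - 1] - series.angle[a]) or 1)
        turns.append(
            HeadTurn(start=int(a), end=int(b), direction=direction, rom=rom, peak_velocity=peak)
        )
    return turns


def summarize_trial(
    turns: Sequence[HeadTurn], condition: str, segment: str, device: str
) -> TrialMetrics:
    """Per-trial averages over the accepted head turns."""
    if len(turns) == 0:
        raise ValueError("no accepted head turns: cannot summarise an empty trial")
    return TrialMetrics(
        condition=condition,
        segment=segment,
        device=device,
        avg_rom=float(np.mean([t.rom for t in turns])),
        avg_peak_velocity=float(np.mean([t.peak_velocity for t in turns])),
        n_turns=len(turns),
    )
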
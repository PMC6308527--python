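"""End-to-end validation runs: both measurement arms, pairing, agreement.

A validation run mirrors the study protocol: for every trial the IMU arm
(sensor fusion → static calibration → plane velocity → integration) and the
motion-capture arm (gap fill → filter → segment frames → resample → Euler →
differentiate) each produce per-trial average ROM and average peak velocity
for head and trunk; locomotor path turns are excluded in walking conditions;
trials are paired per condition and summarised with ICC(A,1), RMSE, percent
error and Bland-Altman statistics.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fileio
from .agreement import AgreementReport, PairedMeasurements, agreement_report, aggregate_conditions
from .imu import FusionParams, estimate_orientation, extract_plane_velocity, integrate_displacement, static_pose_calibration
from .mocap import (
    HEAD_SEGMENT,
    TRUNK_SEGMENT,
    build_segment_frames,
    decompose_segment_angles,
    differentiate_velocity,
    fill_gaps,
    filter_markers,
    resample_series,
)
from .simulate import CONDITIONS, GroundTruth, SyntheticTrialSpec, generate_study_specs, generate_trial
from .streams import ImuStream, MarkerStream, PlaneAngleSeries
from .turns import TrialMetrics, detect_locomotor_turns, segment_head_turns, summarize_trial

__all__ = [
    "RunConfig",
    "TrialRecord",
    "imu_arm_metrics",
    "mocap_arm_metrics",
    "truth_metrics",
    "run_validation",
    "run_validation_from_specs",
    "read_manifest",
    "simulate_study",
    "METRIC_COLUMNS",
]

log = logging.getLogger(__name__)

METRIC_COLUMNS = ["icc_rom", "icc_pv", "rmse_rom", "rmse_pv", "pct_rom", "pct_pv"]
_PRINT_DECIMALS = {
    "icc_rom": 3,
    "icc_pv": 3,
    "rmse_rom": 2,
    "rmse_pv": 2,
    "pct_rom": 1,
    "pct_pv": 1,
}


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the protocol's stated values."""

    fusion: FusionParams = field(default_factory=FusionParams)
    filter_cutoff_hz: float = 6.0
    turn_angle_threshold_deg: float = 45.0
    turn_velocity_threshold_dps: float = 15.0
    min_rom_deg: float = 5.0
    min_peak_dps: float = 10.0
    max_gap_s: float = 0.5
    static_window: Tuple[float, float] = (0.0, 2.9)
    target_rate_hz: float = 128.0
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "filter_cutoff_hz",
            "turn_angle_threshold_deg",
            "turn_velocity_threshold_dps",
            "min_rom_deg",
            "min_peak_dps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrialRecord:
    """Paths and labels of one recorded trial."""

    trial_id: str
    condition: str
    head_imu: str
    trunk_imu: str
    markers: str
    static_start: float = 0.0
    static_end: float = 2.9

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def _condition_plane(condition: str) -> str:
    return "transverse" if condition.endswith("LR") else "sagittal"


def _is_walking(condition: str) -> bool:
    return condition.startswith(("walk", "tandem_walk"))


def _segment_and_summarise(
    series: Dict[str, PlaneAngleSeries],
    heading: PlaneAngleSeries,
    condition: str,
    device: str,
    config: RunConfig,
) -> Dict[str, TrialMetrics]:
    mask = detect_locomotor_turns(
        heading,
        is_walking=_is_walking(condition),
        angle_threshold=config.turn_angle_threshold_deg,
        velocity_threshold=config.turn_velocity_threshold_dps,
    )
    # the static calibration window is not exercise: exclude it so posture
    # wobble around movement onset cannot be counted as a head turn
    mask.mask |= heading.t <= config.static_window[1]
    out = {}
    for segment, ser in series.items():
        turns = segment_head_turns(
            ser, mask, min_rom=config.min_rom_deg, min_peak=config.min_peak_dps
        )
        out[segment] = summarize_trial(turns, condition, segment, device)
    return out


def imu_arm_metrics(
    head: ImuStream,
    trunk: ImuStream,
    condition: str,
    config: Optional[RunConfig] = None,
) -> Dict[str, TrialMetrics]:
    """Per-trial head and trunk metrics from the two IMU streams."""
    config = config or RunConfig()
    plane = _condition_plane(condition)
    series = {}
    heading = None
    for segment, stream in (("head", head), ("trunk", trunk)):
        orient = estimate_orientation(stream, config.fusion)
        corr = static_pose_calibration(orient, config.static_window, stream=stream)
        sel = (stream.t >= config.static_window[0]) & (stream.t <= config.static_window[1])
        bias = stream.gyro[sel].mean(axis=0)
        vel = extract_plane_velocity(stream, orient, corr, plane, segment=segment, bias_dps=bias)
        series[segment] = integrate_displacement(vel)
        if segment == "trunk":
            if plane == "transverse":
                heading = series[segment]
            else:
                hv = extract_plane_velocity(
                    stream, orient, corr, "transverse", segment="trunk", bias_dps=bias
                )
                heading = integrate_displacement(hv)
    return _segment_and_summarise(series, heading, condition, "imu", config)


def mocap_arm_metrics(
    markers: MarkerStream,
    condition: str,
    config: Optional[RunConfig] = None,
) -> Dict[str, TrialMetrics]:
    """Per-trial head and trunk metrics from the optical marker stream."""
    config = config or RunConfig()
    plane = _condition_plane(condition)
    filled = fill_gaps(markers, max_gap=config.max_gap_s)
    filtered = filter_markers(filled, cutoff=config.filter_cutoff_hz)
    series = {}
    heading = None
    for segment, definition in (("head", HEAD_SEGMENT), ("trunk", TRUNK_SEGMENT)):
        frames = build_segment_frames(filtered, definition, static_window=config.static_window)
        frames = resample_series(frames, config.target_rate_hz)
        ang = decompose_segment_angles(frames, plane)
        series[segment] = differentiate_velocity(ang)
        if segment == "trunk":
            if plane == "transverse":
                heading = series[segment]
            else:
                heading = differentiate_velocity(decompose_segment_angles(frames, "transverse"))
    return _segment_and_summarise(series, heading, condition, "mocap", config)


def truth_metrics(truth: GroundTruth, config: Optional[RunConfig] = None) -> Dict[str, TrialMetrics]:
    """Metrics of the noiseless ground-truth kinematics, segmented identically.

    This is the estimation target: the same turn segmentation applied to the
    true plane angle series (which in walking trials includes the gait sway
    that any real sensor would also see).
    """
    config = config or RunConfig()
    series = {
        "head": truth.plane_series("head"),
        "trunk": truth.plane_series("trunk"),
    }
    return _segment_and_summarise(
        series, truth.trunk_heading_series(), truth.spec.condition, "truth", config
    )


def _trial_metrics_frame(rows: List[Tuple[str, str, Dict[str, TrialMetrics]]]) -> pd.DataFrame:
    recs = []
    for trial_id, condition, metrics in rows:
        for segment, m in metrics.items():
            recs.append(
                dict(
                    trial_id=trial_id,
                    condition=condition,
                    segment=segment,
                    device=m.device,
                    avg_rom=m.avg_rom,
                    avg_peak_velocity=m.avg_peak_velocity,
                    n_turns=m.n_turns,
                )
            )
    return pd.DataFrame(recs)


def run_validation(
    records: Sequence[TrialRecord],
    config: Optional[RunConfig] = None,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame], Dict[Tuple[str, str, str], AgreementReport]]:
    """Run both arms on every trial and compute per-condition agreement.

    Returns ``(trial_metrics, summary_tables, reports)``: a tidy per-trial
    metrics table, one summary table per segment (rows = conditions +
    mean/SD-across-conditions, columns = ICC/RMSE/%error for ROM and peak
    velocity), and the full per-(condition, segment, metric) agreement
    reports.  Trials failing any stage are skipped with a logged reason; a
    condition with fewer than 3 valid pairs gets RMSE/%error but no ICC.
    """
    config = config or RunConfig()
    rows: List[Tuple[str, str, Dict[str, TrialMetrics]]] = []
    for rec in records:
        try:
            head = fileio.read_imu_file(rec.head_imu)
            trunk = fileio.read_imu_file(rec.trunk_imu)
            markers = fileio.read_marker_file(rec.markers)
            cfg = dataclasses.replace(config, static_window=(rec.static_start, rec.static_end))
            imu_m = imu_arm_metrics(head, trunk, rec.condition, cfg)
            moc_m = mocap_arm_metrics(markers, rec.condition, cfg)
        except Exception as exc:  # noqa: BLE001 - skip-and-log policy
            log.warning("trial %s skipped: %s", rec.trial_id, exc)
            continue
        rows.append((rec.trial_id, rec.condition, imu_m))
        rows.append((rec.trial_id, rec.condition, moc_m))
    tidy = _trial_metrics_frame(rows)
    summaries, reports = summarize_agreement(tidy)
    return tidy, summaries, reports


def summarize_agreement(
    tidy: pd.DataFrame,
) -> Tuple[Dict[str, pd.DataFrame], Dict[Tuple[str, str, str], AgreementReport]]:
    """Per-condition agreement tables from a tidy per-trial metrics frame."""
    reports: Dict[Tuple[str, str, str], AgreementReport] = {}
    tables: Dict[str, pd.DataFrame] = {}
    for segment in ("head", "trunk"):
        rows = {}
        for condition in CONDITIONS:
            row = {}
            for metric, col in (("rom", "avg_rom"), ("pv", "avg_peak_velocity")):
                sub = tidy[(tidy.condition == condition) & (tidy.segment == segment)]
                a = sub[sub.device == "mocap"].set_index("trial_id")[col]
                b = sub[sub.device == "imu"].set_index("trial_id")[col]
                common = a.index.intersection(b.index)
                if len(common) < 2:
                    row[f"icc_{metric}"] = np.nan
                    row[f"rmse_{metric}"] = np.nan
                    row[f"pct_{metric}"] = np.nan
                    continue
                pairs = PairedMeasurements(
                    a=a.loc[common].to_numpy(),
                    b=b.loc[common].to_numpy(),
                    units=list(common),
                    metric=f"{segment}_{metric}",
                )
                if len(common) >= 3:
                    rep = agreement_report(pairs, condition=condition, metric=f"{segment}_{metric}")
                    reports[(condition, segment, metric)] = rep
                    row[f"icc_{metric}"] = rep.icc
                    row[f"rmse_{metric}"] = rep.rmse
                    row[f"pct_{metric}"] = rep.percent_error
                else:
                    from .agreement import percent_error, rmse as _rmse

                    row[f"icc_{metric}"] = np.nan
                    row[f"rmse_{metric}"] = _rmse(pairs)
                    row[f"pct_{metric}"] = percent_error(pairs)
            rows[condition] = row
        table = pd.DataFrame.from_dict(rows, orient="index")[METRIC_COLUMNS]
        tables[segment] = aggregate_conditions(table)
    return tables, reports


def write_outputs(
    tidy: pd.DataFrame,
    summaries: Dict[str, pd.DataFrame],
    reports: Dict[Tuple[str, str, str], AgreementReport],
    out_dir: str,
) -> None:
    """Write metrics, agreement summaries and Bland-Altman data as CSV."""
    os.makedirs(out_dir, exist_ok=True)
    tidy.to_csv(os.path.join(out_dir, "trial_metrics.csv"), index=False)
    for segment, table in summaries.items():
        display = table.copy()
        for col, dec in _PRINT_DECIMALS.items():
            from .agreement import round_half_away

            display[col] = [
                round_half_away(v, dec) if np.isfinite(v) else v for v in display[col]
            ]
        display.to_csv(os.path.join(out_dir, f"agreement_{segment}.csv"))
    ba = []
    for (condition, segment, metric), rep in reports.items():
        for m, d in zip(rep.ba_mean, rep.ba_diff):
            ba.append(
                dict(
                    condition=condition,
                    segment=segment,
                    metric=metric,
                    pair_mean=m,
                    difference=d,
                    bias=rep.bias,
                    loa_low=rep.loa_low,
                    loa_high=rep.loa_high,
                )
            )
    pd.DataFrame(ba).to_csv(os.path.join(out_dir, "bland_altman.csv"), index=False)


def simulate_study(
    out_dir: str,
    n_subjects: int = 10,
    n_trials: int = 2,
    seed: int = 0,
    conditions: Sequence[str] = CONDITIONS,
    noise_free: bool = False,
    write_hdf5: bool = False,
) -> List[TrialRecord]:
    """Write a complete synthetic study to disk and return its manifest.

    Layout: ``<out_dir>/<subject>/<condition>_t<k>_{head,trunk}.csv``,
    ``..._markers.trc`` and ``..._truth.csv`` per trial, plus a
    ``manifest.csv`` of trial records.
    """
    os.makedirs(out_dir, exist_ok=True)
    specs = generate_study_specs(
        n_subjects=n_subjects, n_trials=n_trials, seed=seed, conditions=conditions, noise_free=noise_free
    )
    records: List[TrialRecord] = []
    for subject, k, spec in specs:
        subj_dir = os.path.join(out_dir, subject)
        os.makedirs(subj_dir, exist_ok=True)
        head, trunk, markers, truth = generate_trial(spec)
        stem = os.path.join(subj_dir, f"{spec.condition}_t{k}")
        if write_hdf5:
            fileio.write_imu_hdf5(head, stem + "_head.h5")
            fileio.write_imu_hdf5(trunk, stem + "_trunk.h5")
            head_path, trunk_path = stem + "_head.h5", stem + "_trunk.h5"
        else:
            fileio.write_imu_csv(head, stem + "_head.csv")
            fileio.write_imu_csv(trunk, stem + "_trunk.csv")
            head_path, trunk_path = stem + "_head.csv", stem + "_trunk.csv"
        fileio.write_trc(markers, stem + "_markers.trc")
        fileio.write_ground_truth_csv(truth, stem + "_truth.csv")
        records.append(
            TrialRecord(
                trial_id=f"{subject}_{spec.condition}_t{k}",
                condition=spec.condition,
                head_imu=head_path,
                trunk_imu=trunk_path,
                markers=stem + "_markers.trc",
            )
        )
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for key in ("head_imu", "trunk_imu", "markers"):
            d[key] = os.path.relpath(d[key], out_dir)  # keep the manifest portable
        rows.append(d)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return records


def run_validation_from_specs(
    specs: Sequence[Tuple[str, int, SyntheticTrialSpec]],
    config: Optional[RunConfig] = None,
    include_truth: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame], Dict[Tuple[str, str, str], AgreementReport]]:
    """Validation run on synthetic trials generated in memory.

    Identical processing to :func:`run_validation` but without the file
    round-trip; with ``include_truth`` the tidy frame also carries the
    ground-truth metrics (device ``"truth"``) for recovery checks.
    """
    config = config or RunConfig()
    rows: List[Tuple[str, str, Dict[str, TrialMetrics]]] = []
    for subject, k, spec in specs:
        trial_id = f"{subject}_{spec.condition}_t{k}"
        try:
            head, trunk, markers, truth = generate_trial(spec)
            imu_m = imu_arm_metrics(head, trunk, spec.condition, config)
            moc_m = mocap_arm_metrics(markers, spec.condition, config)
        except Exception as exc:  # noqa: BLE001 - skip-and-log policy
            log.warning("trial %s skipped: %s", trial_id, exc)
            continue
        rows.append((trial_id, spec.condition, imu_m))
        rows.append((trial_id, spec.condition, moc_m))
        if include_truth:
            rows.append((trial_id, spec.condition, truth_metrics(truth, config)))
    tidy = _trial_metrics_frame(rows)
    summaries, reports = summarize_agreement(tidy)
    return tidy, summaries, reports


def read_manifest(path: str) -> List[TrialRecord]:
    """Trial records from a manifest CSV; relative paths resolve against it."""
    base = os.path.dirname(os.path.abspath(path))
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        for key in ("head_imu", "trunk_imu", "markers"):
            if not os.path.isabs(row[key]):
                row[key] = os.path.join(base, row[key])
        records.append(TrialRecord(**row))
    return records
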
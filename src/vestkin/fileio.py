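"""Readers and writers for IMU streams, marker trajectories and metrics.

IMU data travel as CSV (columns ``t, ax, ay, az, gx, gy, gz, mx, my, mz``,
with ``# key=value`` header comments for rate/units) or HDF5 (datasets of the
same names with attributes).  Marker data use the TRC conventions of optical
motion-capture software (tab-separated, header with marker names and rate,
millimetre units, blank cells for occluded samples).
"""

from __future__ import annotations

import os
from typing import Dict

import numpy as np
import pandas as pd

from .streams import REQUIRED_MARKERS, ImuStream, MarkerStream

__all__ = [
    "write_imu_csv",
    "write_imu_hdf5",
    "read_imu_file",
    "write_trc",
    "read_marker_file",
    "write_ground_truth_csv",
]

G_PER_MS2 = 9.80665

_IMU_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


def write_imu_csv(stream: ImuStream, path: str, accel_units: str = "m/s2") -> None:
    """Write an IMU stream as CSV with a key=value comment header."""
    data = np.column_stack([stream.t, stream.accel, stream.gyro, stream.mag])
    if accel_units == "g":
        data[:, 1:4] /= G_PER_MS2
    elif accel_units != "m/s2":
        raise ValueError("accel_units must be 'm/s2' or 'g'")
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={stream.nominal_rate:g}\n")
        fh.write(f"# accel_units={accel_units}\n")
        fh.write(f"# site={stream.site}\n")
        fh.write(",".join(_IMU_COLS) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.17g")


def write_imu_hdf5(stream: ImuStream, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("t", data=stream.t)
        fh.create_dataset("accel", data=stream.accel)
        fh.create_dataset("gyro", data=stream.gyro)
        fh.create_dataset("mag", data=stream.mag)
        fh.attrs["rate_hz"] = stream.nominal_rate
        fh.attrs["accel_units"] = "m/s2"
        fh.attrs["site"] = stream.site


def _read_imu_csv(path: str) -> ImuStream:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in _IMU_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV {path}: missing columns {missing}")
    accel = df[["ax", "ay", "az"]].to_numpy()
    if meta.get("accel_units", "m/s2") == "g":
        accel = accel * G_PER_MS2
    stream = ImuStream(
        t=df["t"].to_numpy(),
        accel=accel,
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        mag=df[["mx", "my", "mz"]].to_numpy(),
        nominal_rate=float(meta.get("rate_hz", 128.0)),
        site=meta.get("site", ""),
    )
    return stream.validate()


def _read_imu_hdf5(path: str) -> ImuStream:
    import h5py

    with h5py.File(path, "r") as fh:
        accel = fh["accel"][()]
        if fh.attrs.get("accel_units", "m/s2") == "g":
            accel = accel * G_PER_MS2
        site = fh.attrs.get("site", "")
        if isinstance(site, bytes):
            site = site.decode()
        stream = ImuStream(
            t=fh["t"][()],
            accel=accel,
            gyro=fh["gyro"][()],
            mag=fh["mag"][()],
            nominal_rate=float(fh.attrs.get("rate_hz", 128.0)),
            site=str(site),
        )
    return stream.validate()


def read_imu_file(path: str) -> ImuStream:
    """Read and validate an IMU stream from CSV or HDF5 (by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return _read_imu_hdf5(path)
    if ext in (".csv", ".txt"):
        return _read_imu_csv(path)
    raise ValueError(f"unrecognised IMU file extension {ext!r} (expect .csv or .h5)")


def write_trc(stream: MarkerStream, path: str) -> None:
    """Write a marker stream in TRC format (mm units, blank cells for gaps)."""
    names = list(stream.positions)
    n = stream.n
    rate = stream.nominal_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{os.path.basename(path)}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\tmm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        axis_cols = "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(len(names)))
        fh.write("\t\t" + axis_cols + "\n")
        fh.write("\n")
        for i in range(n):
            cells = [str(i + 1), f"{stream.t[i]:.6f}"]
            for name in names:
                p = stream.positions[name][i]
                if np.isnan(p).any():
                    cells.extend(["", "", ""])
                else:
                    cells.extend(f"{v:.6f}" for v in p)
            fh.write("\t".join(cells) + "\n")


def read_marker_file(path: str, required=REQUIRED_MARKERS) -> MarkerStream:
    """Read a marker stream from TRC (or plain wide CSV) and validate it.

    Blank TRC cells become NaN and populate the gap mask.  All six required
    marker names must be present in the header.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".trc":
        return _read_trc(path, required)
    if ext == ".csv":
        return _read_marker_csv(path, required)
    raise ValueError(f"unrecognised marker file extension {ext!r} (expect .trc or .csv)")


def _read_trc(path: str, required) -> MarkerStream:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ValueError(f"TRC file {path} is truncated")
    header_vals = lines[2].split("\t")
    rate = float(header_vals[0])
    name_row = lines[3].split("\t")
    names = [c for c in name_row[2:] if c.strip()]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    t = np.empty(len(data_lines))
    pos = {name: np.full((len(data_lines), 3), np.nan) for name in names}
    for i, ln in enumerate(data_lines):
        cells = ln.split("\t")
        t[i] = float(cells[1])
        for j, name in enumerate(names):
            triple = cells[2 + 3 * j : 5 + 3 * j]
            if len(triple) == 3 and all(c.strip() for c in triple):
                pos[name][i] = [float(c) for c in triple]
    stream = MarkerStream(t=t, positions=pos, nominal_rate=rate)
    return stream.validate(required)


def _read_marker_csv(path: str, required) -> MarkerStream:
    """Wide CSV: column ``t`` plus ``<marker>_x/_y/_z`` triples."""
    df = pd.read_csv(path, comment="#")
    if "t" not in df.columns:
        raise ValueError(f"marker CSV {path}: missing 't' column")
    names = sorted({c.rsplit("_", 1)[0] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    pos = {}
    for name in names:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if all(c in df.columns for c in cols):
            pos[name] = df[cols].to_numpy()
    t = df["t"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    stream = MarkerStream(t=t, positions=pos, nominal_rate=rate)
    return stream.validate(required)


def write_ground_truth_csv(truth, path: str) -> None:
    """True plane kinematics and turn intervals of a synthetic trial."""
    df = pd.DataFrame(
        {
            "t": truth.t,
            "head_yaw": truth.head_euler[:, 0],
            "head_pitch": truth.head_euler[:, 1],
            "head_roll": truth.head_euler[:, 2],
            "trunk_yaw": truth.trunk_euler[:, 0],
            "trunk_pitch": truth.trunk_euler[:, 1],
            "trunk_roll": truth.trunk_euler[:, 2],
            "in_path_turn": truth.turn_sample_mask().astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# condition={truth.spec.condition}\n")
        fh.write(f"# half_cycle_rom={truth.half_cycle_rom:.9g}\n")
        fh.write(f"# peak_velocity={truth.peak_velocity:.9g}\n")
        df.to_csv(fh, index=False, float_format="%.8g")
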
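"""Reading raw IMU recordings from delimited text files.

The on-disk contract is deliberately loose — field deployments produce
tab- or comma-separated dumps with or without a header — so a
:class:`IMUDialect` describes the column layout and units, and
:func:`read_imu` normalizes everything to the package-internal
conventions: time in seconds, acceleration in g, angular velocity in
degrees per second.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError
from .signal import IMURecording

# device measurement range (trunk-worn MEMS unit)
ACCEL_RANGE_G = 8.0
GYRO_RANGE_DPS = 1000.0

_STANDARD_G = 9.80665  # m/s^2


@dataclass
class IMUDialect:
    """Column layout and unit conventions of an IMU text dump.

    Parameters
    ----------
    sep
        Field separator; ``None`` auto-detects (comma/tab/whitespace).
    columns
        Mapping from canonical names ``t, ax, ay, az, gx, gy, gz`` to the
        file's column names. ``None`` takes the first seven numeric
        columns positionally in that order.
    time_unit
        ``"s"`` or ``"ms"``.
    accel_unit
        ``"g"`` or ``"m/s2"``.
    gyro_unit
        ``"deg/s"`` or ``"rad/s"``.
    fs
        Declared sampling rate in Hz.
    max_gap_samples
        Gaps of at most this many consecutive missing samples are
        linearly interpolated; longer gaps are a hard :class:`DataError`.
    """

    sep: str | None = None
    columns: dict[str, str] | None = None
    time_unit: str = "s"
    accel_unit: str = "g"
    gyro_unit: str = "deg/s"
    fs: float = 250.0
    max_gap_samples: int = 5

    @classmethod
    def from_file(cls, path: str | Path) -> "IMUDialect":
        """Load a dialect from a YAML or JSON config file (unknown keys rejected)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"dialect config {path} is not a mapping")
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise FormatError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**raw)


_CANONICAL = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def _has_header(path: Path, sep: str | None) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                break
        else:
            raise FormatError(f"{path}: empty file")
    tokens = re.split(r"[,\t;]|\s+", line)
    for tok in tokens:
        if not tok:
            continue
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_imu(path: str | Path, dialect: IMUDialect | None = None) -> IMURecording:
    """Read a delimited IMU file into an :class:`IMURecording` (frame="sensor").

    Raises
    ------
    FormatError
        Missing columns or unparseable file.
    DataError
        Non-monotone time, gaps longer than ``dialect.max_gap_samples``
        samples, or values outside the device range.
    """
    dialect = dialect or IMUDialect()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    header = _has_header(path, dialect.sep)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.sep,
            engine="python",
            header=0 if header else None,
            comment="#",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if dialect.columns is not None:
        missing = [c for c in _CANONICAL if dialect.columns.get(c) not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns for {missing}")
        df = df[[dialect.columns[c] for c in _CANONICAL]]
    else:
        num = df.apply(pd.to_numeric, errors="coerce")
        numeric_cols = [c for c in num.columns if num[c].notna().all()]
        if len(numeric_cols) < 7:
            raise FormatError(
                f"{path}: need >= 7 numeric columns (t, ax..az, gx..gz), "
                f"found {len(numeric_cols)}"
            )
        df = num[numeric_cols[:7]]

    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise DataError(f"{path}: non-numeric values in data columns")

    t = arr[:, 0]
    if dialect.time_unit == "ms":
        t = t / 1000.0
    elif dialect.time_unit != "s":
        raise FormatError(f"unknown time_unit {dialect.time_unit!r}")

    accel = arr[:, 1:4]
    if dialect.accel_unit == "m/s2":
        accel = accel / _STANDARD_G
    elif dialect.accel_unit != "g":
        raise FormatError(f"unknown accel_unit {dialect.accel_unit!r}")

    gyro = arr[:, 4:7]
    if dialect.gyro_unit == "rad/s":
        gyro = np.degrees(gyro)
    elif dialect.gyro_unit != "deg/s":
        raise FormatError(f"unknown gyro_unit {dialect.gyro_unit!r}")

    dt = np.diff(t)
    if len(t) < 2 or np.any(dt <= 0):
        raise DataError(f"{path}: time not strictly increasing")

    fs = float(dialect.fs)
    nominal = 1.0 / fs
    gaps = dt > 1.5 * nominal
    if gaps.any():
        n_missing = np.round(dt[gaps] * fs).astype(int) - 1
        if (n_missing > dialect.max_gap_samples).any():
            raise DataError(
                f"{path}: gap of {int(n_missing.max())} samples exceeds "
                f"max_gap_samples={dialect.max_gap_samples}"
            )
        # re-grid short gaps by linear interpolation
        t_uniform = t[0] + np.arange(round((t[-1] - t[0]) * fs) + 1) / fs
        accel = np.column_stack([np.interp(t_uniform, t, accel[:, i]) for i in range(3)])
        gyro = np.column_stack([np.interp(t_uniform, t, gyro[:, i]) for i in range(3)])
        t = t_uniform
        dt = np.diff(t)

    if np.any(np.abs(dt - nominal) > 0.01 * nominal):
        raise DataError(f"{path}: sample spacing deviates >1% from 1/fs={nominal:.6f}s")

    if np.abs(accel).max() > ACCEL_RANGE_G:
        raise DataError(f"{path}: acceleration exceeds device range +/-{ACCEL_RANGE_G} g")
    if np.abs(gyro).max() > GYRO_RANGE_DPS:
        raise DataError(f"{path}: angular velocity exceeds +/-{GYRO_RANGE_DPS} deg/s")

    return IMURecording(time=t, accel=accel, gyro=gyro, fs=fs, frame="sensor")


def write_imu_csv(rec: IMURecording, path: str | Path) -> None:
    """Write a recording in the canonical 7-column CSV dialect (header row)."""
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.accel, rec.gyro]),
        columns=list(_CANONICAL),
    )
    df.to_csv(path, index=False, float_format="%.6f")
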
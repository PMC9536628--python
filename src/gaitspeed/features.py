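"""IMU-derived gait features: cadence, vertical height displacement (VHD)
of the center of mass, and trunk roll/yaw excursions.

VHD follows the displacement reading — per step, the difference between
the maximum and minimum vertical CoM height obtained by double
integration of the gravity-removed vertical acceleration, averaged over
steps, in cm. Drift is controlled per step by mean-removal of the
acceleration, re-zeroing of the mean velocity and a linear detrend of
position, rather than a high-pass filter whose cutoff would be one more
free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import GaitError, InsufficientDataError
from .signal import (
    DEFAULT_MIN_STEP_INTERVAL_S,
    DEFAULT_PROMINENCE_G,
    DEFAULT_SMOOTH_WINDOW,
    IMURecording,
    StepEvent,
    StrideSeries,
    TrimPolicy,
    assign_sides,
    build_strides,
    detect_steps,
    hanning_smooth,
    integrate_yaw_angle,
    reorient_to_cartesian,
    trim_steady_state,
)

G_CM_S2 = 980.665  # cm/s^2 per g


def _remove_endpoint_line(seg: np.ndarray) -> np.ndarray:
    """Subtract the line through the segment's first and last samples.

    Removes integration drift (constant offsets and linear ramps)
    exactly, and — unlike a least-squares detrend — leaves a
    whole-period sinusoid unchanged, so the excursion of a periodic
    gait cycle is not inflated by a fitted slope.
    """
    n = len(seg)
    line = seg[0] + (seg[-1] - seg[0]) * np.arange(n) / (n - 1)
    return seg - line


@dataclass(frozen=True)
class GaitFeatures:
    """The four regression predictors derived from one walk, plus counts."""

    cadence: float  # steps/min
    vhd: float  # cm
    roll_angle: float  # deg, mean per-stride max-min excursion
    yaw_angle: float  # deg
    n_steps: int
    mean_step_time: float  # s

    def as_dict(self) -> dict[str, float]:
        return {
            "cadence": self.cadence,
            "vhd": self.vhd,
            "roll_angle": self.roll_angle,
            "yaw_angle": self.yaw_angle,
            "n_steps": self.n_steps,
            "mean_step_time": self.mean_step_time,
        }


def compute_cadence(steps: Sequence[StepEvent]) -> float:
    """Steps per minute: 60 * (n-1) / (t_last - t_first)."""
    steps = list(steps)
    if len(steps) < 2:
        raise InsufficientDataError("cadence needs at least 2 steps")
    span = steps[-1].time - steps[0].time
    return 60.0 * (len(steps) - 1) / span


def compute_vhd(
    rec: IMURecording,
    steps: Sequence[StepEvent],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Mean per-step vertical CoM excursion (max - min height), in cm.

    Per step interval (between consecutive step events, endpoints
    included): subtract the interval-mean acceleration (gravity plus
    bias), integrate twice with trapezoids, re-zero mean velocity,
    remove the endpoint-to-endpoint position line, and take max - min.
    Steps shorter than 4 samples are skipped; if all are skipped the
    walk is insufficient.

    By construction the result is invariant to any constant acceleration
    offset and any linear-in-time velocity drift.
    """
    steps = list(steps)
    if len(steps) < 2:
        raise InsufficientDataError("VHD needs at least 2 steps")
    window = min(smooth_window, len(rec.time) if len(rec.time) % 2 else len(rec.time) - 1)
    az = hanning_smooth(rec.vertical_accel(), window) * G_CM_S2
    t = rec.time
    excursions = []
    for s0, s1 in zip(steps[:-1], steps[1:]):
        i0, i1 = s0.index, s1.index
        if i1 - i0 + 1 < 4:
            continue
        a = az[i0 : i1 + 1]
        a = a - a.mean()
        v = cumulative_trapezoid(a, t[i0 : i1 + 1], initial=0.0)
        v = v - v.mean()
        z = cumulative_trapezoid(v, t[i0 : i1 + 1], initial=0.0)
        z = _remove_endpoint_line(z)
        excursions.append(z.max() - z.min())
    if not excursions:
        raise InsufficientDataError("no step interval long enough for VHD")
    return float(np.mean(excursions))


def compute_angle_excursions(
    rec: IMURecording,
    strides: StrideSeries,
) -> tuple[float, float]:
    """Mean per-stride (max - min) roll and yaw angle excursions in degrees.

    Roll-axis (forward, x) and yaw-axis (vertical, z) angular velocities
    are integrated to angle series; per stride, the line through the
    segment endpoints is removed — constant gyro bias integrates to a
    ramp, which this cancels exactly — before taking max - min.
    Returns (roll, yaw).
    """
    if strides.n_strides < 1:
        raise InsufficientDataError("angle excursions need at least one complete stride")
    roll_series = cumulative_trapezoid(rec.gyro[:, 0], rec.time, initial=0.0)
    yaw_series = cumulative_trapezoid(rec.gyro[:, 2], rec.time, initial=0.0)
    roll_exc, yaw_exc = [], []
    for p0, p1 in strides.strides:
        i0 = strides.steps[p0].index
        i1 = strides.steps[p1].index
        if i1 - i0 + 1 < 4:
            continue
        for series, out in ((roll_series, roll_exc), (yaw_series, yaw_exc)):
            seg = _remove_endpoint_line(series[i0 : i1 + 1])
            out.append(seg.max() - seg.min())
    if not roll_exc:
        raise InsufficientDataError("no stride long enough for angle excursions")
    return float(np.mean(roll_exc)), float(np.mean(yaw_exc))


@dataclass
class FeatureConfig:
    """Preprocessing and extraction parameters for the full feature chain."""

    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL_S
    prominence: float = DEFAULT_PROMINENCE_G
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    still_window: tuple[float, float] | str = "auto"


def extract_features(
    rec: IMURecording,
    config: FeatureConfig | None = None,
) -> tuple[GaitFeatures, list[dict]]:
    """Run the full chain: reorient -> smooth/detect -> sides -> trim ->
    cadence/VHD/angles. Returns the features and a provenance log (one
    record per stage). Stage failures re-raise with the stage named.
    """
    config = config or FeatureConfig()
    log: list[dict] = []

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except GaitError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
        log.append({"stage": name, "ok": True})
        return out

    if rec.frame == "sensor":
        rec = stage("reorient", reorient_to_cartesian, rec, config.still_window)
    steps = stage(
        "detect",
        detect_steps,
        rec,
        config.min_step_interval,
        config.prominence,
        config.smooth_window,
    )
    if len(steps) < 2:
        raise InsufficientDataError("[detect] no steps detected in recording")
    log[-1]["n_steps"] = len(steps)
    yaw_series = stage("yaw_index", integrate_yaw_angle, rec)
    steps = stage("sides", assign_sides, steps, yaw_series)
    rec, steps = stage("trim", trim_steady_state, rec, steps, config.trim)
    strides = build_strides(steps)
    cadence = stage("cadence", compute_cadence, steps)
    vhd = stage("vhd", compute_vhd, rec, steps, config.smooth_window)
    roll, yaw = stage("angles", compute_angle_excursions, rec, strides)
    feats = GaitFeatures(
        cadence=cadence,
        vhd=vhd,
        roll_angle=roll,
        yaw_angle=yaw,
        n_steps=len(steps),
        mean_step_time=(steps[-1].time - steps[0].time) / (len(steps) - 1),
    )
    return feats, log
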
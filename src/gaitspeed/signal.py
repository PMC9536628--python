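"""Core IMU signal handling: recording container, re-orientation,
smoothing, step detection, side assignment and steady-state trimming.

Coordinate conventions after re-orientation (``frame == "cartesian"``):
x = forward (direction of progression), y = lateral, z = vertical (up).
Acceleration is in g and includes gravity (+1 g on z when upright);
angular velocity is in deg/s about the same axes, so roll rate lives on
x (mediolateral sway is a rotation about the forward axis) and yaw rate
on z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend, find_peaks
from scipy.spatial.transform import Rotation

from .errors import (
    DataError,
    InsufficientDataError,
    OrientationError,
    ParameterError,
)

Side = Literal["left", "right", "unknown"]

#: default Hann smoothing window: 0.1 s at 250 Hz — passes the step-frequency
#: band (<= 3 Hz) while suppressing broadband sensor noise
DEFAULT_SMOOTH_WINDOW = 25
DEFAULT_MIN_STEP_INTERVAL_S = 0.3  # cadence ceiling 200 steps/min
DEFAULT_PROMINENCE_G = 0.05
YAW_TIE_DEG = 0.1  # |yaw| below this at a step gives no lateralizing information


@dataclass
class IMURecording:
    """A time-stamped tri-axial IMU trace.

    ``time`` in s (strictly increasing, ~uniform), ``accel`` (n, 3) in g,
    ``gyro`` (n, 3) in deg/s, ``fs`` in Hz, ``frame`` either ``"sensor"``
    (raw axes) or ``"cartesian"`` (x forward, y lateral, z up).
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float = 250.0
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.time)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError("accel and gyro must be (n, 3) arrays matching time")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def vertical_accel(self) -> np.ndarray:
        """Gravity-axis (z) acceleration in g; requires cartesian frame."""
        if self.frame != "cartesian":
            raise ParameterError("recording must be in the cartesian frame")
        return self.accel[:, 2]


@dataclass(frozen=True)
class StepEvent:
    """One gait step: the sample index and time of its acceleration peak."""

    index: int
    time: float
    side: Side = "unknown"


@dataclass
class StrideSeries:
    """Ordered steps plus stride boundaries (pairs of step-list positions).

    A stride spans exactly two steps: same-side consecutive steps when
    sides are known, otherwise every second step.
    """

    steps: list[StepEvent]
    strides: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def hanning_smooth(signal: np.ndarray, window_samples: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Zero-phase Hann-weighted moving average, same length as the input.

    The window must be a positive odd integer no longer than the series;
    edges are reflect-padded so walk boundaries are not amplitude-biased.
    A window of 1 is the identity.
    """
    x = np.asarray(signal, dtype=float)
    if window_samples <= 0 or window_samples % 2 == 0:
        raise ParameterError("window_samples must be a positive odd integer")
    if window_samples > len(x):
        raise ParameterError("window_samples exceeds series length")
    if window_samples == 1:
        return x.copy()
    w = np.hanning(window_samples)
    if w.sum() == 0:  # window 2 would hit this; excluded by the odd check
        return x.copy()
    w = w / w.sum()
    half = window_samples // 2
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, w, mode="valid")


def _rotation_to_vertical(mean_accel: np.ndarray) -> Rotation:
    norm = np.linalg.norm(mean_accel)
    if norm < 0.2:  # free-fall-like; gravity direction unrecoverable
        raise OrientationError(
            f"mean acceleration magnitude {norm:.3f} g too small to locate gravity"
        )
    ghat = mean_accel / norm
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [ghat])
    return rot


def reorient_to_cartesian(
    rec: IMURecording,
    still_window: tuple[float, float] | str = "auto",
) -> IMURecording:
    """Rotate a sensor-frame recording into the cartesian gait frame.

    The vertical axis is aligned with the mean acceleration (gravity)
    over ``still_window`` — a (t0, t1) interval in seconds, or ``"auto"``
    for the whole recording, which over whole strides of steady walking
    averages to gravity. The forward axis is the first principal
    direction of the horizontal acceleration, signed so that the mean
    forward jerk at detected vertical-acceleration peaks is positive.
    The same rotation is applied to the gyroscope axes, so the transform
    is an isometry of both signals.
    """
    if rec.frame != "sensor":
        raise ParameterError("recording is already in the cartesian frame")
    if isinstance(still_window, str):
        if still_window != "auto":
            raise ParameterError(f"unknown still_window {still_window!r}")
        sel = slice(None)
    else:
        t0, t1 = still_window
        if t1 - t0 < 1.0:
            raise ParameterError("still_window must span at least 1 s")
        sel = (rec.time >= t0) & (rec.time <= t1)
        if not np.any(sel):
            raise ParameterError("still_window outside recording")

    r1 = _rotation_to_vertical(rec.accel[sel].mean(axis=0))
    accel = r1.apply(rec.accel)
    gyro = r1.apply(rec.gyro)

    # forward axis: principal direction of horizontal acceleration
    horiz = accel[:, :2] - accel[:, :2].mean(axis=0)
    cov = horiz.T @ horiz
    if np.trace(cov) / max(len(horiz), 1) > 1e-8:
        evals, evecs = np.linalg.eigh(cov)
        u = evecs[:, np.argmax(evals)]
        yaw = np.arctan2(u[1], u[0])
        r2 = Rotation.from_euler("z", -yaw)
        accel = r2.apply(accel)
        gyro = r2.apply(gyro)

        # sign disambiguation: mean forward jerk at vertical-accel peaks > 0
        az_s = hanning_smooth(accel[:, 2], min(DEFAULT_SMOOTH_WINDOW, _odd_floor(len(accel))))
        peaks, _ = find_peaks(
            az_s,
            distance=max(1, round(DEFAULT_MIN_STEP_INTERVAL_S * rec.fs)),
            prominence=DEFAULT_PROMINENCE_G,
        )
        if len(peaks) > 0:
            jerk = np.gradient(accel[:, 0], rec.time)
            if jerk[peaks].mean() < 0:
                flip = Rotation.from_euler("z", np.pi)
                accel = flip.apply(accel)
                gyro = flip.apply(gyro)

    mean_vert = accel[sel, 2].mean()
    if not (0.8 <= mean_vert <= 1.2):
        raise OrientationError(
            f"mean vertical acceleration {mean_vert:.3f} g after re-orientation "
            "is not near +1 g"
        )
    return replace(rec, accel=accel, gyro=gyro, frame="cartesian")


def _odd_floor(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def detect_steps(
    rec: IMURecording,
    min_step_interval: float = DEFAULT_MIN_STEP_INTERVAL_S,
    prominence: float = DEFAULT_PROMINENCE_G,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[StepEvent]:
    """Identify steps as peaks of the smoothed vertical acceleration.

    Returns one event per step (possibly empty — a flat signal is not an
    error), with sides ``unknown`` until :func:`assign_sides` runs.
    """
    if not rec.fs or rec.fs <= 0:
        raise ParameterError("recording has no valid sampling rate")
    az = hanning_smooth(rec.vertical_accel(), min(smooth_window, _odd_floor(rec.n_samples)))
    peaks, _ = find_peaks(
        az,
        distance=max(1, round(min_step_interval * rec.fs)),
        prominence=prominence,
    )
    return [StepEvent(index=int(i), time=float(rec.time[i])) for i in peaks]


def integrate_yaw_angle(rec: IMURecording) -> np.ndarray:
    """Integrated, linearly detrended yaw angle series in degrees.

    The detrend removes constant gyro bias (which integrates to a ramp);
    what remains is the oscillatory trunk-rotation component whose sign
    at each step lateralizes it.
    """
    if rec.frame != "cartesian":
        raise ParameterError("recording must be in the cartesian frame")
    angle = cumulative_trapezoid(rec.gyro[:, 2], rec.time, initial=0.0)
    return detrend(angle, type="linear")


def assign_sides(steps: Sequence[StepEvent], yaw_series: np.ndarray) -> list[StepEvent]:
    """Label steps left/right from the sign of the yaw angle at each step.

    Sides are assigned only when the yaw sign strictly alternates across
    all steps and no step sits in the tie band (|yaw| < 0.1 deg);
    otherwise every side stays ``unknown`` — degenerate yaw carries no
    lateralizing information and is not an error.
    """
    steps = list(steps)
    if not steps:
        return []
    yaw_at = np.array([yaw_series[s.index] for s in steps])
    if np.any(np.abs(yaw_at) < YAW_TIE_DEG):
        return [replace(s, side="unknown") for s in steps]
    signs = np.sign(yaw_at)
    if len(signs) > 1 and np.any(signs[1:] * signs[:-1] >= 0):
        return [replace(s, side="unknown") for s in steps]
    label = {1.0: "left", -1.0: "right"}
    return [replace(s, side=label[sg]) for s, sg in zip(steps, signs)]


@dataclass
class TrimPolicy:
    """Steady-state trimming policy.

    ``mode="steps"`` drops ``n_trim`` steps at each end (the default two
    approximates the 2 m acceleration/deceleration exclusions at a
    typical older-adult step length of ~0.6 m); ``mode="seconds"`` drops
    ``seconds`` of recording at each end before re-selecting steps.
    """

    mode: str = "steps"
    n_trim: int = 2
    seconds: float = 1.0


def trim_steady_state(
    rec: IMURecording,
    steps: Sequence[StepEvent],
    policy: TrimPolicy | None = None,
) -> tuple[IMURecording, list[StepEvent]]:
    """Remove acceleration/deceleration phases; re-index retained events.

    The recording is cropped to the span of the retained steps. Fewer
    than 4 retained steps raise :class:`InsufficientDataError`.
    """
    policy = policy or TrimPolicy()
    steps = list(steps)
    if policy.mode == "steps":
        n = policy.n_trim
        if len(steps) < 2 * n + 2:
            raise InsufficientDataError(
                f"{len(steps)} steps; need >= {2 * n + 2} to trim {n} at each end"
            )
        kept = steps[n : len(steps) - n] if n > 0 else steps
    elif policy.mode == "seconds":
        t0 = rec.time[0] + policy.seconds
        t1 = rec.time[-1] - policy.seconds
        kept = [s for s in steps if t0 <= s.time <= t1]
    else:
        raise ParameterError(f"unknown trim mode {policy.mode!r}")

    if len(kept) < 4:
        raise InsufficientDataError(f"only {len(kept)} steps remain after trimming (< 4)")

    i0, i1 = kept[0].index, kept[-1].index
    cropped = replace(
        rec,
        time=rec.time[i0 : i1 + 1],
        accel=rec.accel[i0 : i1 + 1],
        gyro=rec.gyro[i0 : i1 + 1],
    )
    reindexed = [replace(s, index=s.index - i0) for s in kept]
    return cropped, reindexed


def build_strides(steps: Sequence[StepEvent]) -> StrideSeries:
    """Pair steps into strides.

    With known sides, a stride joins consecutive same-side steps; with
    unknown sides it joins every second step — identical pairings when
    sides strictly alternate.
    """
    steps = list(steps)
    strides: list[tuple[int, int]] = []
    sides_known = steps and all(s.side in ("left", "right") for s in steps)
    if sides_known:
        by_side: dict[str, list[int]] = {"left": [], "right": []}
        for pos, s in enumerate(steps):
            by_side[s.side].append(pos)
        for positions in by_side.values():
            strides.extend(zip(positions[:-1], positions[1:]))
        strides.sort()
    else:
        strides = [(i, i + 2) for i in range(len(steps) - 2)]
    return StrideSeries(steps=steps, strides=strides)
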
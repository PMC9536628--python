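import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gaitspeed.errors import InsufficientDataError, OrientationError, ParameterError
from gaitspeed.signal import (
    IMURecording,
    StepEvent,
    TrimPolicy,
    assign_sides,
    build_strides,
    detect_steps,
    hanning_smooth,
    integrate_yaw_angle,
    reorient_to_cartesian,
    trim_steady_state,
)
from gaitspeed.slip import WalkSpec, simulate_walk


def _cartesian_walk_like(n=3000, fs=250.0, f_step=2.0):
    """A gravity-aligned recording with the simulator's signal morphology:
    vertical-acceleration peaks where sin is -1, forward jerk positive there."""
    t = np.arange(n) / fs
    az = 1.0 - 0.25 * np.sin(2 * np.pi * f_step * t)
    ax = 0.05 * np.cos(2 * np.pi * f_step * t)
    ay = 0.03 * np.sin(np.pi * f_step * t)
    accel = np.column_stack([ax, ay, az])
    gyro = np.column_stack([np.zeros(n), np.zeros(n), 20 * np.sin(np.pi * f_step * t)])
    return IMURecording(time=t, accel=accel, gyro=gyro, fs=fs, frame="sensor")


class TestHanningSmooth:
    def test_constant_preserved(self):
        out = hanning_smooth(np.full(100, 3.7), 25)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_impulse_gives_normalized_hann(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = hanning_smooth(x, 25)
        w = np.hanning(25)
        w = w / w.sum()
        np.testing.assert_allclose(out[38:63], w, atol=1e-12)

    def test_noise_variance_reduced(self, rng):
        x = rng.standard_normal(5000)
        assert hanning_smooth(x, 25).var() < x.var()

    @pytest.mark.parametrize("window", [0, -3, 4, 10])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ParameterError):
            hanning_smooth(np.zeros(50), window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            hanning_smooth(np.zeros(10), 25)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(200), r.standard_normal(200)
        lhs = hanning_smooth(a * x + b * y, 25)
        rhs = a * hanning_smooth(x, 25) + b * hanning_smooth(y, 25)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestReorient:
    def test_aligned_recording_unchanged(self):
        rec = _cartesian_walk_like()
        out = reorient_to_cartesian(rec)
        assert out.frame == "cartesian"
        np.testing.assert_allclose(out.accel, rec.accel, atol=1e-9)
        np.testing.assert_allclose(out.gyro, rec.gyro, atol=1e-9)

    @pytest.mark.parametrize("euler", [(8, 4, 12), (-15, 6, 40), (2, -9, -70)])
    def test_known_rotation_inverted(self, euler):
        rec = _cartesian_walk_like()
        rot = Rotation.from_euler("xyz", euler, degrees=True)
        rotated = IMURecording(time=rec.time, accel=rot.apply(rec.accel),
                               gyro=rot.apply(rec.gyro), fs=rec.fs, frame="sensor")
        out = reorient_to_cartesian(rotated)
        mean = out.accel.mean(axis=0)
        angle = np.degrees(np.arccos(mean[2] / np.linalg.norm(mean)))
        assert angle < 1.0
        assert 0.95 <= out.accel[:, 2].mean() <= 1.05

    def test_isometry(self):
        rec = _cartesian_walk_like()
        rot = Rotation.from_euler("xyz", (20, -10, 35), degrees=True)
        rotated = IMURecording(time=rec.time, accel=rot.apply(rec.accel),
                               gyro=rot.apply(rec.gyro), fs=rec.fs, frame="sensor")
        out = reorient_to_cartesian(rotated)
        np.testing.assert_allclose(
            np.linalg.norm(out.accel, axis=1),
            np.linalg.norm(rotated.accel, axis=1),
            rtol=1e-9,
        )

    def test_free_fall_like_is_orientation_error(self):
        n = 500
        t = np.arange(n) / 250
        rec = IMURecording(time=t, accel=1e-3 * np.ones((n, 3)) / 3,
                           gyro=np.zeros((n, 3)), fs=250, frame="sensor")
        with pytest.raises(OrientationError):
            reorient_to_cartesian(rec)


class TestDetectSteps:
    def test_two_hz_oscillation_gives_twenty_steps(self):
        n, fs = 2500, 250.0
        t = np.arange(n) / fs
        az = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        rec = IMURecording(time=t, accel=np.column_stack([np.zeros(n), np.zeros(n), az]),
                           gyro=np.zeros((n, 3)), fs=fs, frame="cartesian")
        steps = detect_steps(rec)
        assert abs(len(steps) - 20) <= 1
        spacings = np.diff([s.time for s in steps])
        np.testing.assert_allclose(spacings, 0.5, atol=0.02)

    def test_flat_signal_gives_no_steps(self):
        n = 1000
        rec = IMURecording(time=np.arange(n) / 250.0,
                           accel=np.column_stack([np.zeros(n)] * 2 + [np.ones(n)]),
                           gyro=np.zeros((n, 3)), fs=250, frame="cartesian")
        assert detect_steps(rec) == []

    @pytest.mark.parametrize("f", [1.4, 1.9, 2.6])
    def test_sinusoid_count_matches_frequency(self, f):
        n, fs = 2500, 250.0
        t = np.arange(n) / fs
        az = 1.0 + 0.3 * np.sin(2 * np.pi * f * t)
        rec = IMURecording(time=t, accel=np.column_stack([np.zeros(n), np.zeros(n), az]),
                           gyro=np.zeros((n, 3)), fs=fs, frame="cartesian")
        assert abs(len(detect_steps(rec)) - round(f * 10)) <= 1

    def test_simulator_truth_within_20ms(self, default_walk):
        rec = reorient_to_cartesian(default_walk.recording)
        steps = detect_steps(rec)
        truth = default_walk.step_times
        hits = 0
        for st_time in truth:
            if np.min(np.abs(np.array([s.time for s in steps]) - st_time)) <= 0.020:
                hits += 1
        assert hits / len(truth) >= 0.95


class TestAssignSides:
    def _steps(self, times, fs=250.0):
        return [StepEvent(index=int(round(tt * fs)), time=tt) for tt in times]

    def test_antiphase_yaw_alternates(self):
        fs = 250.0
        t = np.arange(2500) / fs
        yaw = 5.0 * np.sin(2 * np.pi * 1.0 * t)  # stride-frequency sway
        steps = self._steps([0.25 + k for k in range(9)] + [0.75 + k for k in range(9)])
        steps = sorted(steps, key=lambda s: s.time)
        out = assign_sides(steps, yaw)
        sides = [s.side for s in out]
        assert set(sides) == {"left", "right"}
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_zero_yaw_gives_unknown(self):
        yaw = np.zeros(2500)
        steps = self._steps([0.5, 1.0, 1.5, 2.0])
        assert all(s.side == "unknown" for s in assign_sides(steps, yaw))

    def test_simulator_sides_recovered(self, clean_walk):
        rec = reorient_to_cartesian(clean_walk.recording)
        steps = detect_steps(rec)
        yaw = integrate_yaw_angle(rec)
        out = assign_sides(steps, yaw)
        # compare against ground truth at matched step times
        matched = 0
        for s in out:
            k = int(np.argmin(np.abs(clean_walk.step_times - s.time)))
            matched += s.side == clean_walk.sides[k]
        assert matched / len(out) == 1.0


class TestTrimAndStrides:
    def _steps(self, n, dt=0.5):
        return [StepEvent(index=int(k * dt * 250), time=k * dt) for k in range(n)]

    def test_trim_two_steps_each_end(self):
        n = 3000
        rec = IMURecording(time=np.arange(n) / 250.0, accel=np.zeros((n, 3)),
                           gyro=np.zeros((n, 3)), fs=250, frame="cartesian")
        steps = self._steps(20)
        cropped, kept = trim_steady_state(rec, steps, TrimPolicy(mode="steps", n_trim=2))
        assert len(kept) == 16
        assert kept[0].time == steps[2].time  # first retained is original third step
        assert kept[0].index == 0  # re-indexed to the cropped recording
        assert cropped.time[0] == steps[2].time

    def test_too_few_steps_raises(self):
        n = 1000
        rec = IMURecording(time=np.arange(n) / 250.0, accel=np.zeros((n, 3)),
                           gyro=np.zeros((n, 3)), fs=250, frame="cartesian")
        with pytest.raises(InsufficientDataError):
            trim_steady_state(rec, self._steps(5), TrimPolicy(mode="steps", n_trim=2))

    def test_ramp_walk_trimmed_cadence_closer_to_commanded(self):
        spec = WalkSpec(seed=0, ramp_s=3.0, duration=14.0,
                        noise_accel=1e-9, noise_gyro=1e-9)
        walk = simulate_walk(spec)
        rec = reorient_to_cartesian(walk.recording)
        steps = detect_steps(rec)
        cad_raw = 60.0 * (len(steps) - 1) / (steps[-1].time - steps[0].time)
        _, kept = trim_steady_state(rec, steps, TrimPolicy(mode="steps", n_trim=4))
        cad_trim = 60.0 * (len(kept) - 1) / (kept[-1].time - kept[0].time)
        assert abs(cad_trim - spec.cadence) < abs(cad_raw - spec.cadence)

    def test_stride_pairing_known_sides(self):
        steps = [StepEvent(index=i * 125, time=i * 0.5,
                           side="left" if i % 2 == 0 else "right") for i in range(6)]
        strides = build_strides(steps)
        assert strides.strides == [(0, 2), (1, 3), (2, 4), (3, 5)]

    def test_stride_pairing_unknown_sides_every_second_step(self):
        steps = [StepEvent(index=i * 125, time=i * 0.5) for i in range(5)]
        strides = build_strides(steps)
        assert strides.strides == [(0, 2), (1, 3), (2, 4)]
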
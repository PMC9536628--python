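"""Spring-loaded inverted-pendulum (SLIP) analytics and synthetic data.

The SLIP stance model gives closed-form step-length geometry — with leg
length ``l1``, leg-bending coefficient at contact ``beta0 = beta1(0)``
and span-leg half-angle ``a`` from vertical, the step length is
``2 * l1 * beta0 * sin(a)``; normalized by height via the leg/height
ratio ``alpha1`` this is ``2 * alpha1 * beta0 * sin(a)``. The energy
conserved across a step contact decreases as step length grows, which is
why longer steps need more external work per step.

The walk simulator is kinematic, not a forward SLIP integration: it
prescribes CoM trajectories (vertical sinusoid at step frequency with
peak-to-peak equal to the commanded VHD, roll/yaw sinusoids at stride
frequency with commanded per-stride excursions), differentiates them to
sensor signals, adds gravity, seeded noise and an optional known
misalignment rotation. That is exactly what is needed to ground-truth
the preprocessing and feature extractors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .models import (
    SUBGROUP_NAMES,
    LinearSpeedModel,
    NSLSubgroupModel,
    assign_nsl_subgroup,
    compute_nsl,
    compute_step_length,
)
from .signal import IMURecording

G_CM_S2 = 980.665


@dataclass(frozen=True)
class SLIPParams:
    """Pendulum parameters. Lengths in cm, mass kg, angles deg, omega rad/s."""

    m1: float
    l1: float
    beta0: float
    a: float
    omega1: float
    alpha1: float
    height: float

    def __post_init__(self) -> None:
        if not (0 < self.beta0 <= 1):
            raise ParameterError("beta0 must be in (0, 1]")
        if not (0 <= self.a < 90):
            raise ParameterError("span-leg angle a must be in [0, 90) degrees")
        if abs(self.l1 - self.alpha1 * self.height) > 0.01 * self.l1:
            raise ParameterError("l1 must equal alpha1 * height within 1%")


def slip_step_length(l1: float, beta0: float, a: float) -> float:
    """Step length 2 * l1 * beta0 * sin(a); l1 in cm, a in degrees."""
    if not (0 <= a < 90):
        raise ParameterError("span-leg angle a must be in [0, 90) degrees")
    return 2.0 * l1 * beta0 * np.sin(np.radians(a))


def slip_nsl(alpha1: float, beta0: float, a: float) -> float:
    """Normalized step length 2 * alpha1 * beta0 * sin(a) (dimensionless)."""
    if not (0 <= a < 90):
        raise ParameterError("span-leg angle a must be in [0, 90) degrees")
    return 2.0 * alpha1 * beta0 * np.sin(np.radians(a))


def conserved_energy(m1: float, l_l: float, omega1: float, l_s: float) -> float:
    """Energy conserved across step contact, in joules (SI lengths, m).

    E = 1/2 * m1 * l_l^2 * omega1^2 * [1 - (l_s^2 / (4 l_l^2))^2].
    Strictly decreasing in l_s on (0, 2*l_l); zero at l_s = 2*l_l.
    """
    if not (0 <= l_s <= 2 * l_l):
        raise ParameterError("step length must satisfy 0 <= l_s <= 2*l_l")
    ratio = l_s**2 / (4.0 * l_l**2)
    return 0.5 * m1 * l_l**2 * omega1**2 * (1.0 - ratio**2)


@dataclass(frozen=True)
class WalkSpec:
    """Commanded ground truth for one synthetic walk.

    Defaults are the marginal means of the reference cohort of healthy
    older adults walking at a comfortable pace. Noise levels are
    realistic trunk-MEMS values well above the device quantization.
    """

    speed: float = 114.4  # cm/s
    cadence: float = 115.5  # steps/min
    vhd: float = 3.29  # cm peak-to-peak per step
    roll_amp: float = 6.4  # deg per-stride excursion
    yaw_amp: float = 12.2  # deg per-stride excursion
    duration: float = 12.0  # s
    fs: float = 250.0
    noise_accel: float = 0.02  # g RMS per axis
    noise_gyro: float = 1.0  # deg/s RMS per axis
    seed: int = 0
    misalign_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ramp_s: float = 0.0  # step-frequency ramp-up duration at walk start

    def __post_init__(self) -> None:
        for name in ("speed", "cadence", "vhd", "roll_amp", "yaw_amp", "duration", "fs"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def to_json(self) -> dict:
        d = self.__dict__.copy()
        d["misalign_deg"] = list(self.misalign_deg)
        return d


@dataclass
class SyntheticWalk:
    """A generated recording plus its commanded truth and step annotations."""

    recording: IMURecording
    truth: WalkSpec
    step_times: np.ndarray  # s
    sides: list[str]


def simulate_walk(spec: WalkSpec) -> SyntheticWalk:
    """Generate a ground-truthed IMU recording of steady walking.

    The vertical CoM displacement is a sinusoid at step frequency with
    peak-to-peak ``vhd``; forward (0.05 g) and lateral (0.03 g)
    acceleration oscillations make the forward axis identifiable; roll
    and yaw angles are stride-frequency sinusoids whose per-stride
    excursions equal the commanded amplitudes, phased so the yaw sign
    alternates across steps (the side ground truth). A ``ramp_s`` > 0
    ramps the step frequency from 70% of commanded over the first
    ``ramp_s`` seconds. Identical seeds give bit-identical recordings.
    """
    f = spec.cadence / 60.0  # step frequency, Hz
    amp_g = (spec.vhd / 2.0) * (2 * np.pi * f) ** 2 / G_CM_S2
    if amp_g > 0.5:
        raise ParameterError(
            f"vhd/cadence imply a {amp_g:.2f} g vertical oscillation (> 0.5 g)"
        )

    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    if spec.ramp_s > 0:
        freq = f * (0.7 + 0.3 * np.minimum(t / spec.ramp_s, 1.0))
        phi = 2 * np.pi * np.concatenate([[0.0], np.cumsum((freq[1:] + freq[:-1]) / 2) / spec.fs])
    else:
        phi = 2 * np.pi * f * t

    z = (spec.vhd / 2.0) * np.sin(phi)  # cm
    az = np.gradient(np.gradient(z, t), t) / G_CM_S2 + 1.0  # g, incl. gravity
    ax = 0.05 * np.cos(phi)
    ay = 0.03 * np.sin(phi / 2.0)
    accel = np.column_stack([ax, ay, az])

    stride_phase = phi / 2.0
    roll = (spec.roll_amp / 2.0) * np.sin(stride_phase)
    yaw = (spec.yaw_amp / 2.0) * np.sin(stride_phase - np.pi / 4.0)
    gyro = np.column_stack(
        [np.gradient(roll, t), np.zeros(n), np.gradient(yaw, t)]
    )

    # ground-truth step times: vertical-acceleration peaks, phi = 3pi/2 + 2k pi
    targets = np.arange(3 * np.pi / 2, phi[-1], 2 * np.pi)
    step_times = np.interp(targets, phi, t)
    yaw_at_steps = (spec.yaw_amp / 2.0) * np.sin(targets / 2.0 - np.pi / 4.0)
    sides = ["left" if y > 0 else "right" for y in yaw_at_steps]

    rng = np.random.default_rng(spec.seed)
    accel = accel + rng.normal(0.0, spec.noise_accel, accel.shape)
    gyro = gyro + rng.normal(0.0, spec.noise_gyro, gyro.shape)

    if any(spec.misalign_deg):
        rot = Rotation.from_euler("xyz", spec.misalign_deg, degrees=True)
        accel = rot.apply(accel)
        gyro = rot.apply(gyro)

    rec = IMURecording(time=t, accel=accel, gyro=gyro, fs=spec.fs, frame="sensor")
    return SyntheticWalk(recording=rec, truth=spec, step_times=step_times, sides=sides)


# ---------------------------------------------------------------------------
# synthetic cohorts


def _reference() -> dict:
    with resources.files("gaitspeed.data").joinpath("cohort_reference.json").open() as fh:
        return json.load(fh)


_FEATURE_BOUNDS = {
    "age": (40, 110),
    "height": (120, 210),
    "weight": (30, 150),
    "foot_length": (18, 32),
    "cadence": (40, 200),
    "vhd": (0.3, 10),
    "roll_angle": (0.3, 25),
    "yaw_angle": (0.3, 40),
}
_CONTINUOUS = list(_FEATURE_BOUNDS)


def _sample_block(
    rng: np.random.Generator,
    n: int,
    marg: dict,
    correlation: np.ndarray | None,
) -> pd.DataFrame:
    means = np.array([marg[f][0] for f in _CONTINUOUS])
    sds = np.array([marg[f][1] for f in _CONTINUOUS])
    if correlation is None:
        z = rng.standard_normal((n, len(_CONTINUOUS)))
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (len(_CONTINUOUS), len(_CONTINUOUS)):
            raise ParameterError(
                f"correlation must be {len(_CONTINUOUS)}x{len(_CONTINUOUS)} "
                f"over {_CONTINUOUS}"
            )
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("correlation matrix not positive definite") from exc
        z = rng.standard_normal((n, len(_CONTINUOUS))) @ chol.T
    x = means + sds * z
    for j, feat in enumerate(_CONTINUOUS):
        lo, hi = _FEATURE_BOUNDS[feat]
        x[:, j] = np.clip(x[:, j], lo, hi)
    df = pd.DataFrame(x, columns=_CONTINUOUS)
    df["sex"] = np.where(rng.random(n) < marg["female_fraction"], 2, 1)
    return df


def generate_cohort(
    n: int,
    generator_model: LinearSpeedModel | NSLSubgroupModel,
    residual_sd: float = 5.0,
    seed: int | None = None,
    marginals: dict | None = None,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample a synthetic cohort table with a known generating model.

    Profiles and features are drawn from independent truncated-normal
    marginals (defaults: the reference cohort's printed means/SDs; a
    correlation matrix over the continuous features may be supplied).
    ``reference_speed`` is the generator model's prediction plus
    N(0, residual_sd) noise, emulating the instrumented-walkway reading.

    With an :class:`NSLSubgroupModel` generator, features are drawn from
    a mixture of the three subgroups' marginals (reference subgroup
    proportions), giving the cohort real NSL structure; each subject is
    then routed exactly as the study defines subgroups — base-model
    speed -> step length -> NSL -> nearest centroid — and the routed
    submodel generates the reference speed. The routing is stored in a
    ``true_subgroup`` column for pipeline-recovery experiments.
    """
    if n < 50:
        raise ParameterError("cohort generation needs n >= 50")
    if residual_sd < 0:
        raise ParameterError("residual_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ref = _reference()

    if isinstance(generator_model, NSLSubgroupModel):
        sub_ref = ref["subgroups"]
        probs = np.array([sub_ref[s]["n"] for s in SUBGROUP_NAMES], dtype=float)
        probs /= probs.sum()
        groups = rng.choice(len(SUBGROUP_NAMES), size=n, p=probs)
        frames = []
        for g, name in enumerate(SUBGROUP_NAMES):
            ng = int((groups == g).sum())
            if ng == 0:
                continue
            marg = dict(sub_ref[name])
            if marginals:
                marg.update(marginals)
            frames.append(_sample_block(rng, ng, marg, correlation))
        df = pd.concat(frames, ignore_index=True)
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        # route each subject as the study defines subgroups: base-model
        # speed -> NSL -> nearest centroid; the routed submodel generates
        # the reference speed
        records = df.to_dict(orient="records")
        base_speed = np.array([generator_model.base.predict(r) for r in records])
        nsl = np.array(
            [
                compute_nsl(compute_step_length(s, r["cadence"]), r["height"])
                for s, r in zip(base_speed, records)
            ]
        )
        routed = [assign_nsl_subgroup(v, generator_model.centroids) for v in nsl]
        df["true_subgroup"] = routed
        preds = np.array(
            [
                generator_model.submodels[sub].predict(r)
                for sub, r in zip(routed, records)
            ]
        )
    else:
        marg = dict(ref["all"])
        if marginals:
            marg.update(marginals)
        df = _sample_block(rng, n, marg, correlation)
        preds = np.array(
            [generator_model.predict(row) for row in df.to_dict(orient="records")]
        )

    noise = rng.normal(0.0, residual_sd, n) if residual_sd > 0 else np.zeros(n)
    df["reference_speed"] = preds + noise
    df.insert(0, "participant_id", [f"S{i:05d}" for i in range(len(df))])
    return df
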
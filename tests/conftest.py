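import numpy as np
import pytest

from gaitspeed.features import GaitFeatures
from gaitspeed.models import ParticipantProfile, load_model
from gaitspeed.slip import WalkSpec, simulate_walk

# printed marginal means of the reference cohort and its NSL subgroups,
# used across tests as known inputs
COHORT_MEANS = {
    "all": dict(age=73.9, sex=2, height=159.8, weight=61.6, foot_length=23.4,
                cadence=115.5, vhd=3.29, roll_angle=6.4, yaw_angle=12.2,
                gait_speed=114.4),
    "short": dict(age=76.7, sex=2, height=159.7, weight=62.3, foot_length=23.0,
                  cadence=109.9, vhd=2.53, roll_angle=4.92, yaw_angle=9.56,
                  gait_speed=95.1),
    "medium": dict(age=73.2, sex=2, height=160.4, weight=62.0, foot_length=23.5,
                   cadence=116.4, vhd=3.24, roll_angle=6.42, yaw_angle=12.07,
                   gait_speed=115.5),
    "long": dict(age=72.6, sex=2, height=158.8, weight=60.1, foot_length=23.7,
                 cadence=119.2, vhd=4.14, roll_angle=7.79, yaw_angle=15.15,
                 gait_speed=130.9),
}


def profile_features(group: str) -> tuple[ParticipantProfile, GaitFeatures]:
    m = COHORT_MEANS[group]
    profile = ParticipantProfile(age=m["age"], sex=m["sex"], height=m["height"],
                                 weight=m["weight"], foot_length=m["foot_length"])
    feats = GaitFeatures(cadence=m["cadence"], vhd=m["vhd"],
                         roll_angle=m["roll_angle"], yaw_angle=m["yaw_angle"],
                         n_steps=20, mean_step_time=60.0 / m["cadence"])
    return profile, feats


@pytest.fixture(scope="session")
def model0():
    return load_model("model0")


@pytest.fixture(scope="session")
def model1():
    return load_model("model1")


@pytest.fixture(scope="session")
def model2():
    return load_model("model2")


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free, alignment-free synthetic walk at cohort-mean gait."""
    spec = WalkSpec(seed=0, noise_accel=1e-12, noise_gyro=1e-12)
    return simulate_walk(spec)


@pytest.fixture(scope="session")
def default_walk():
    """Default-noise walk with a known sensor misalignment."""
    spec = WalkSpec(seed=0, misalign_deg=(8.0, 4.0, 12.0))
    return simulate_walk(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
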
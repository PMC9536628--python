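"""Gait-speed prediction models.

Three linear regressions estimate comfortable-pace gait speed (cm/s) of
healthy older adults from anthropometrics and trunk-IMU gait features:

* ``model0`` — age, sex (male=1, female=2), cadence, VHD, foot length;
* ``model1`` — age, cadence, VHD, foot length, weight, roll and yaw
  trunk-angle excursions (sex drops out);
* ``model2`` — three normalized-step-length (NSL) subgroup-specific
  regressions over the model1 feature set. A new subject is routed by
  the model1 speed: step length = speed * 60 / cadence, NSL = step
  length / height, then nearest NSL centroid (ties to the lower
  subgroup).

Coefficients ship as versioned JSON assets so refitted models are
drop-in replacements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ModelInputError, ParameterError
from .features import GaitFeatures

SUBGROUP_NAMES = ("short", "medium", "long")


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometrics. Units: age yr, height cm, weight kg, foot_length cm
    (mean of both feet); sex coded male=1, female=2."""

    age: float
    sex: int
    height: float
    weight: float
    foot_length: float

    def __post_init__(self) -> None:
        checks = [
            ("age", self.age, 40, 110),
            ("height", self.height, 120, 210),
            ("weight", self.weight, 30, 150),
            ("foot_length", self.foot_length, 18, 32),
        ]
        for name, val, lo, hi in checks:
            if not (lo <= val <= hi):
                raise ParameterError(f"{name}={val} outside [{lo}, {hi}]")
        if self.sex not in (1, 2):
            raise ParameterError("sex must be 1 (male) or 2 (female)")

    def as_dict(self) -> dict[str, float]:
        return {
            "age": self.age,
            "sex": self.sex,
            "height": self.height,
            "weight": self.weight,
            "foot_length": self.foot_length,
        }


@dataclass(frozen=True)
class LinearSpeedModel:
    """Affine gait-speed model: intercept (cm/s) plus named coefficients."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    response_units: str = "cm/s"

    @property
    def feature_list(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, predictors: Mapping[str, float]) -> float:
        total = self.intercept
        for feat, coef in self.coefficients.items():
            if feat not in predictors or predictors[feat] is None:
                raise ModelInputError(f"model {self.name!r} requires predictor {feat!r}")
            value = float(predictors[feat])
            if not np.isfinite(value):
                raise ModelInputError(f"predictor {feat!r} is not finite")
            total += coef * value
        return float(total)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "response_units": self.response_units,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "LinearSpeedModel":
        return cls(
            name=obj["name"],
            intercept=float(obj["intercept"]),
            coefficients={k: float(v) for k, v in obj["coefficients"].items()},
            response_units=obj.get("response_units", "cm/s"),
        )


@dataclass(frozen=True)
class NSLSubgroupModel:
    """NSL-routed subgroup model: a base (model1) plus three submodels.

    ``centroids`` are the three NSL cluster centers, strictly increasing;
    ``centroid_sds`` the within-cluster SDs used to flag extrapolation.
    """

    base: LinearSpeedModel
    centroids: tuple[float, float, float]
    submodels: dict[str, LinearSpeedModel]
    centroid_sds: tuple[float, float, float] | None = None
    name: str = "model2"

    def __post_init__(self) -> None:
        if len(self.centroids) != 3 or not np.all(np.diff(self.centroids) > 0):
            raise ParameterError("centroids must be three strictly increasing values")
        if set(self.submodels) != set(SUBGROUP_NAMES):
            raise ParameterError(f"submodels must be exactly {SUBGROUP_NAMES}")

    def to_json(self) -> dict:
        out = {
            "name": self.name,
            "response_units": self.base.response_units,
            "base": self.base.to_json(),
            "centroids": list(self.centroids),
            "submodels": {k: m.to_json() for k, m in self.submodels.items()},
        }
        if self.centroid_sds is not None:
            out["centroid_sds"] = list(self.centroid_sds)
        return out


@dataclass(frozen=True)
class Model2Prediction:
    """Full subgroup-model output: final speed plus routing diagnostics."""

    speed: float  # cm/s
    subgroup: str
    nsl: float
    model1_speed: float
    extrapolated: bool  # NSL beyond centroid span +/- 3 subgroup SDs


def _bundled(name: str) -> dict:
    with resources.files("gaitspeed.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_model(source: str | Path) -> LinearSpeedModel | NSLSubgroupModel:
    """Load a model from a bundled name ("model0", "model1", "model2")
    or a JSON file path."""
    if isinstance(source, str) and source in ("model0", "model1", "model2"):
        obj = _bundled(f"{source}.json")
    else:
        with open(source) as fh:
            obj = json.load(fh)
    if "submodels" in obj:
        base = obj["base"]
        base_model = (
            LinearSpeedModel.from_json(_bundled(f"{base}.json"))
            if isinstance(base, str)
            else LinearSpeedModel.from_json(base)
        )
        sds = obj.get("centroid_sds")
        return NSLSubgroupModel(
            base=base_model,
            centroids=tuple(obj["centroids"]),
            submodels={k: LinearSpeedModel.from_json(v) for k, v in obj["submodels"].items()},
            centroid_sds=tuple(sds) if sds else None,
            name=obj.get("name", "model2"),
        )
    return LinearSpeedModel.from_json(obj)


def _predictors(profile: ParticipantProfile, f: GaitFeatures) -> dict[str, float]:
    d = profile.as_dict()
    d.update(f.as_dict())
    return d


def predict_model0(
    profile: ParticipantProfile,
    f: GaitFeatures,
    model: LinearSpeedModel | None = None,
) -> float:
    """Baseline model speed in cm/s."""
    model = model or load_model("model0")
    return model.predict(_predictors(profile, f))


def predict_model1(
    profile: ParticipantProfile,
    f: GaitFeatures,
    model: LinearSpeedModel | None = None,
) -> float:
    """Extended model speed in cm/s (sex unused)."""
    model = model or load_model("model1")
    return model.predict(_predictors(profile, f))


def compute_step_length(speed: float, cadence: float) -> float:
    """Step length in cm: speed (cm/s) * 60 / cadence (steps/min)."""
    if cadence <= 0:
        raise ParameterError("cadence must be positive")
    return speed * 60.0 / cadence


def compute_nsl(step_length: float, height: float) -> float:
    """Normalized step length: step length / body height (both cm)."""
    if height <= 0:
        raise ParameterError("height must be positive")
    return step_length / height


def assign_nsl_subgroup(
    nsl: float,
    centroids: tuple[float, float, float],
) -> str:
    """Nearest-centroid subgroup label; ties go to the lower subgroup."""
    centroids = tuple(centroids)
    if len(centroids) != 3 or not np.all(np.diff(centroids) > 0):
        raise ParameterError("centroids must be three strictly increasing values")
    if not np.isfinite(nsl):
        raise ParameterError("NSL must be finite")
    dists = [abs(nsl - c) for c in centroids]
    return SUBGROUP_NAMES[int(np.argmin(dists))]  # argmin takes first on ties


def predict_model2(
    profile: ParticipantProfile,
    f: GaitFeatures,
    model: NSLSubgroupModel | None = None,
) -> Model2Prediction:
    """Subgroup-specific speed: model1 -> NSL -> nearest centroid -> submodel.

    Extrapolation (NSL beyond the centroid span widened by 3 subgroup
    SDs) still returns a prediction but sets ``extrapolated``.
    """
    model = model or load_model("model2")
    predictors = _predictors(profile, f)
    speed1 = model.base.predict(predictors)
    nsl = compute_nsl(compute_step_length(speed1, f.cadence), profile.height)
    subgroup = assign_nsl_subgroup(nsl, model.centroids)
    speed = model.submodels[subgroup].predict(predictors)
    extrapolated = False
    if model.centroid_sds is not None:
        lo = model.centroids[0] - 3 * model.centroid_sds[0]
        hi = model.centroids[2] + 3 * model.centroid_sds[2]
        extrapolated = not (lo <= nsl <= hi)
    return Model2Prediction(
        speed=speed,
        subgroup=subgroup,
        nsl=nsl,
        model1_speed=speed1,
        extrapolated=extrapolated,
    )
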
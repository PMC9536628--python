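"""Model-development pipeline: VIF-screened ordinary least squares,
exact 1-D k-means on normalized step length, and subgroup refitting.

The collinearity screen iteratively drops the worst predictor while any
variance inflation factor is at or above the threshold (default 2.5),
then fits OLS. The 1-D k-means is solved exactly by dynamic programming
over the sorted values — deterministic and globally optimal, so the
published-pipeline reproduction carries no Lloyd-iteration seed
sensitivity (a seed argument is accepted for API symmetry only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, ParameterError
from .models import (
    SUBGROUP_NAMES,
    LinearSpeedModel,
    NSLSubgroupModel,
    compute_nsl,
    compute_step_length,
)

DEFAULT_VIF_THRESHOLD = 2.5

MODEL1_FEATURES = [
    "age",
    "cadence",
    "vhd",
    "foot_length",
    "weight",
    "roll_angle",
    "yaw_angle",
]

#: columns a cohort table must provide for the full pipeline
COHORT_COLUMNS = MODEL1_FEATURES + ["sex", "height", "reference_speed"]


def validate_cohort(cohort: pd.DataFrame, columns: Sequence[str] | None = None) -> None:
    columns = list(columns) if columns is not None else COHORT_COLUMNS
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ParameterError(f"cohort table missing columns: {missing}")
    if cohort[columns].isna().any().any():
        raise ParameterError("cohort table has missing values in modeling columns")


@dataclass
class FitReport:
    """OLS fit summary mirroring the development-table layout.

    ``table`` has one row per retained feature (plus the constant) with
    unstandardized beta, SE, standardized B, p and VIF.
    """

    model: LinearSpeedModel
    r: float
    r2: float
    adjusted_r2: float
    f_stat: float
    n: int
    table: pd.DataFrame
    dropped: list[str]

    def to_json(self) -> dict:
        return {
            "model": self.model.to_json(),
            "r": self.r,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "f_stat": self.f_stat,
            "n": self.n,
            "dropped": self.dropped,
            "table": self.table.to_dict(orient="records"),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R²_j) from
    regressing column j (with intercept) on the remaining columns.

    Perfect collinearity reports +inf; a constant column is an error.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ParameterError("VIF needs at least 2 predictors")
    X = design.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [c for c, s in zip(cols, X.std(axis=0)) if s == 0]
        raise ParameterError(f"constant predictor column(s): {const}")
    out = {}
    for j, col in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_linear_model(
    cohort: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
    name: str = "fitted",
) -> FitReport:
    """VIF-screened OLS of ``response`` on ``candidates``.

    While any VIF >= threshold the worst offender is dropped; the
    surviving set is fit by OLS (statsmodels). Raises if screening
    empties the candidate set or n < p + 2.
    """
    candidates = list(candidates)
    validate_cohort(cohort, candidates + [response])
    if len(cohort) < len(candidates) + 2:
        raise InsufficientDataError(
            f"n={len(cohort)} too small for {len(candidates)} candidate predictors"
        )
    kept = candidates[:]
    dropped: list[str] = []
    while len(kept) >= 2:
        vifs = compute_vif(cohort[kept])
        if vifs.max() < vif_threshold:
            break
        worst = vifs.idxmax()
        kept.remove(worst)
        dropped.append(worst)
    if not kept:
        raise ParameterError("VIF screening removed every candidate predictor")
    if len(cohort) < len(kept) + 2:
        raise InsufficientDataError(
            f"n={len(cohort)} too small for {len(kept)} predictors"
        )

    X = sm.add_constant(cohort[kept].to_numpy(dtype=float))
    y = cohort[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()

    sd_x = cohort[kept].std(ddof=1).to_numpy()
    sd_y = y.std(ddof=1)
    std_b = res.params[1:] * sd_x / sd_y
    vifs = compute_vif(cohort[kept]) if len(kept) >= 2 else pd.Series({kept[0]: 1.0})

    rows = [
        {
            "feature": "const",
            "beta": res.params[0],
            "se": res.bse[0],
            "std_b": np.nan,
            "p": res.pvalues[0],
            "vif": np.nan,
        }
    ]
    for i, feat in enumerate(kept):
        rows.append(
            {
                "feature": feat,
                "beta": res.params[i + 1],
                "se": res.bse[i + 1],
                "std_b": std_b[i],
                "p": res.pvalues[i + 1],
                "vif": vifs[feat],
            }
        )
    model = LinearSpeedModel(
        name=name,
        intercept=float(res.params[0]),
        coefficients={feat: float(res.params[i + 1]) for i, feat in enumerate(kept)},
    )
    r2 = float(res.rsquared)
    return FitReport(
        model=model,
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adjusted_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        n=int(res.nobs),
        table=pd.DataFrame(rows),
        dropped=dropped,
    )


def kmeans_1d(
    values: Sequence[float],
    k: int = 3,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means by dynamic programming.

    Globally minimizes the within-cluster sum of squares; clusters are
    contiguous in sorted order (a property of the 1-D optimum). Returns
    (centroids ascending, labels aligned with the input order). ``seed``
    is accepted for API symmetry but unused — the solution is exact.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("values must be one-dimensional")
    if len(np.unique(x)) < k:
        raise ParameterError(f"need at least k={k} distinct values, got {len(np.unique(x))}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)

    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-segment SS for xs[i..j], vectorized over start indices i
        m = j - i + 1
        s = s1[j + 1] - s1[i]
        q = s2[j + 1] - s2[i]
        return q - s * s / m

    D = np.full((k, n), np.inf)
    B = np.zeros((k, n), dtype=int)
    D[0, :] = s2[1:] - s1[1:] ** 2 / (np.arange(n) + 1)
    for c in range(1, k):
        for i in range(c, n):
            starts = np.arange(c, i + 1)
            costs = D[c - 1, starts - 1] + seg_cost(starts, i)
            best = int(np.argmin(costs))
            D[c, i] = costs[best]
            B[c, i] = starts[best]

    boundaries = np.empty(k + 1, dtype=int)
    boundaries[k] = n
    i = n - 1
    for c in range(k - 1, 0, -1):
        start = B[c, i]
        boundaries[c] = start
        i = start - 1
    boundaries[0] = 0

    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for c in range(k):
        lo, hi = boundaries[c], boundaries[c + 1]
        labels_sorted[lo:hi] = c
        centroids[c] = xs[lo:hi].mean()

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centroids, labels


@dataclass
class Model2FitResult:
    """Everything the subgroup pipeline produces."""

    model: NSLSubgroupModel
    base_report: FitReport
    subgroup_reports: dict[str, FitReport]
    nsl: np.ndarray
    labels: np.ndarray  # 0=short, 1=medium, 2=long, aligned with cohort rows


def fit_model2_pipeline(cohort: pd.DataFrame, seed: int | None = None) -> Model2FitResult:
    """Single-pass subgroup pipeline.

    1. VIF-screened OLS of reference speed on the model1 candidate set.
    2. Per-subject NSL from the fitted model's speed, cadence and height.
    3. Exact 1-D k-means (k=3) on NSL.
    4. Refit the retained feature set within each subgroup (no
       re-screening; VIFs are still reported).
    """
    validate_cohort(cohort)
    base_report = fit_linear_model(
        cohort, "reference_speed", MODEL1_FEATURES, name="model1_refit"
    )
    speeds = np.array(
        [base_report.model.predict(row) for row in cohort.to_dict(orient="records")]
    )
    nsl = np.array(
        [
            compute_nsl(compute_step_length(s, c), h)
            for s, c, h in zip(speeds, cohort["cadence"], cohort["height"])
        ]
    )
    centroids, labels = kmeans_1d(nsl, k=3, seed=seed)

    features = base_report.model.feature_list
    reports: dict[str, FitReport] = {}
    submodels: dict[str, LinearSpeedModel] = {}
    sds = []
    for c, name in enumerate(SUBGROUP_NAMES):
        sub = cohort[labels == c]
        if len(sub) < len(features) + 2:
            raise InsufficientDataError(
                f"subgroup {name!r} has n={len(sub)} < {len(features) + 2}"
            )
        rep = fit_linear_model(
            sub,
            "reference_speed",
            features,
            vif_threshold=np.inf,  # feature set fixed by the base model
            name=f"model2_{name}",
        )
        reports[name] = rep
        submodels[name] = rep.model
        sds.append(float(nsl[labels == c].std(ddof=1)))

    model = NSLSubgroupModel(
        base=base_report.model,
        centroids=tuple(centroids),
        submodels=submodels,
        centroid_sds=tuple(sds),
        name="model2_refit",
    )
    return Model2FitResult(
        model=model,
        base_report=base_report,
        subgroup_reports=reports,
        nsl=nsl,
        labels=labels,
    )
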
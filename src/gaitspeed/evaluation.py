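"""Agreement between estimated and reference gait speeds.

Metrics follow the validation-study convention: percent errors relative
to the reference (gold-standard) speed, RMSE in cm/s, and an intraclass
correlation coefficient. The ICC defaults to the two-way random,
single-rater, absolute-agreement form ICC(2,1) — device-vs-reference
agreement is an absolute question — with ICC(3,1) (consistency)
available via ``form="consistency"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .errors import InsufficientDataError, ParameterError

STRATA = ("slow", "medium", "fast")


def _paired(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ParameterError("est and ref must be 1-D arrays of equal length")
    return est, ref


def percent_errors(est: Sequence[float], ref: Sequence[float]) -> tuple[float, float]:
    """Signed and absolute mean percent error relative to the reference.

    e_i = 100 * (est_i - ref_i) / ref_i; returns (ME, MAE) = (mean e,
    mean |e|). Any non-positive reference is an error.
    """
    est, ref = _paired(est, ref)
    if len(est) < 1:
        raise ParameterError("need at least one pair")
    if np.any(ref <= 0):
        raise ParameterError("reference speeds must be positive")
    e = 100.0 * (est - ref) / ref
    return float(e.mean()), float(np.abs(e).mean())


def rmse(est: Sequence[float], ref: Sequence[float]) -> float:
    """Root mean square error in cm/s."""
    est, ref = _paired(est, ref)
    if len(est) < 1:
        raise ParameterError("need at least one pair")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def icc(
    est: Sequence[float],
    ref: Sequence[float],
    form: str = "absolute",
) -> tuple[float, float, float]:
    """Two-way ICC between estimates and references with its 95% CI.

    ``form="absolute"`` gives ICC(2,1) (two-way random, absolute
    agreement); ``form="consistency"`` gives ICC(3,1). Needs >= 3 pairs
    and variance in at least one rater.
    """
    est, ref = _paired(est, ref)
    if len(est) < 3:
        raise InsufficientDataError("ICC needs at least 3 pairs")
    if est.std() == 0 and ref.std() == 0:
        raise ParameterError("ICC undefined: zero variance in both measurements")
    if form == "absolute":
        labels = ("ICC(A,1)", "ICC2")  # McGraw-Wong / Shrout-Fleiss naming
    elif form == "consistency":
        labels = ("ICC(C,1)", "ICC3")
    else:
        raise ParameterError(f"unknown ICC form {form!r}")
    n = len(est)
    data = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["est", "ref"], n),
            "score": np.concatenate([est, ref]),
        }
    )
    with warnings.catch_warnings():
        # degenerate tables (zero error mean square) divide by zero inside
        # the ANOVA; the ICC itself is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            table = pg.intraclass_corr(
                data=data, targets="target", raters="rater", ratings="score"
            ).set_index("Type")
    label = next(lb for lb in labels if lb in table.index)
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), float(lo), float(hi)


def speed_strata(ref: Sequence[float]) -> np.ndarray:
    """Label each reference speed slow/medium/fast by mean +/- 1 SD.

    Slow: below mean - SD; fast: above mean + SD; medium otherwise
    (population SD; with zero spread everything is medium).
    """
    ref = np.asarray(ref, dtype=float)
    if len(ref) < 2:
        raise ParameterError("strata need at least 2 values")
    mu, sd = ref.mean(), ref.std(ddof=0)
    labels = np.full(len(ref), "medium", dtype=object)
    labels[ref < mu - sd] = "slow"
    labels[ref > mu + sd] = "fast"
    return labels


@dataclass
class EvaluationReport:
    """Agreement metrics for one model within one speed stratum."""

    model: str
    stratum: str
    n: int
    me_pct: float | None
    mae_pct: float | None
    rmse_cm_s: float | None
    icc: float | None
    icc_ci: tuple[float, float] | None
    icc_form: str = "absolute"


def evaluate_models(
    est_by_model: Mapping[str, Sequence[float]],
    ref: Sequence[float],
    icc_form: str = "absolute",
) -> pd.DataFrame:
    """One row per (model, stratum in slow/medium/fast/all).

    Strata come from the reference speeds. Empty strata yield n=0 rows
    with null metrics; strata with fewer than 3 pairs report errors but
    a null ICC.
    """
    ref = np.asarray(ref, dtype=float)
    labels = speed_strata(ref)
    rows = []
    for model, est in est_by_model.items():
        est = np.asarray(est, dtype=float)
        if est.shape != ref.shape:
            raise ParameterError(f"estimates for {model!r} length-mismatch reference")
        for stratum in STRATA + ("all",):
            mask = np.ones(len(ref), bool) if stratum == "all" else labels == stratum
            n = int(mask.sum())
            rec = {"model": model, "stratum": stratum, "n": n, "icc_form": icc_form}
            if n == 0:
                rec.update(me_pct=None, mae_pct=None, rmse_cm_s=None, icc=None,
                           icc_ci_low=None, icc_ci_high=None)
            else:
                me, mae = percent_errors(est[mask], ref[mask])
                rec.update(me_pct=me, mae_pct=mae, rmse_cm_s=rmse(est[mask], ref[mask]))
                if n >= 3 and not (est[mask].std() == 0 and ref[mask].std() == 0):
                    val, lo, hi = icc(est[mask], ref[mask], form=icc_form)
                    rec.update(icc=val, icc_ci_low=lo, icc_ci_high=hi)
                else:
                    rec.update(icc=None, icc_ci_low=None, icc_ci_high=None)
            rows.append(rec)
    return pd.DataFrame(rows)
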
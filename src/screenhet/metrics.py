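"""Discrimination and calibration metrics for screening-benefit models.

* ``c_statistic`` -- ordinary concordance for lung-cancer mortality: the
  probability that a randomly chosen death received a higher predicted risk
  than a randomly chosen survivor (ties count one half).
* ``c_for_benefit`` -- concordance for *benefit*: CT and control records are
  each sorted by predicted benefit and matched 1:1 by rank; a pair's observed
  benefit is ``outcome(control) - outcome(CT)`` (1: benefit, 0: neutral,
  -1: harm) and its predicted benefit is the pair mean.  The statistic is the
  concordance between predicted and observed pair benefit over pairs with
  differing observed benefit.  Pure-noise predictions typically land between
  0.40 and 0.60.
* ``calibration_for_benefit`` -- records are grouped by predicted-benefit
  quantiles; within each group the observed benefit is the control-minus-CT
  event-rate difference (absolute scale) or one minus the event-rate ratio
  (relative scale, with the exact conditional-binomial machinery supplying
  the CI); a group-size-weighted least-squares line of observed on predicted
  benefit summarizes calibration (slope 1, intercept 0 is ideal).
* ``external_validate`` -- recomputes all metrics and standardized estimates
  for a *frozen* model on another cohort, without recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .results import EffectEstimate


@dataclass
class BenefitEvaluation:
    """Discrimination/calibration summary for one model on one cohort."""

    c_statistic: float
    c_for_benefit: float
    n_pairs: int
    calibration_groups: pd.DataFrame
    calibration_slope: float
    calibration_intercept: float
    scale: str = "absolute"
    notes: list[str] = field(default_factory=list)


def c_statistic(predicted_risk: np.ndarray, outcome: np.ndarray) -> float:
    """Concordance probability; ties in predictions count one half.

    Returns NaN (with a warning) when outcomes are all events or all
    non-events.
    """
    import warnings

    pred = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(outcome).astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("c_statistic undefined: outcomes are all one class")
        return float("nan")
    ranks = rankdata(pred)  # midranks handle ties
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _pairwise_auc(pred_hi: np.ndarray, pred_lo: np.ndarray) -> tuple[float, int]:
    """Mann-Whitney concordance of pred_hi over pred_lo, count of pairs."""
    n1, n0 = len(pred_hi), len(pred_lo)
    if n1 == 0 or n0 == 0:
        return 0.0, 0
    ranks = rankdata(np.r_[pred_hi, pred_lo])
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc) * n1 * n0, n1 * n0


def match_benefit_pairs(predicted_benefit: np.ndarray, arm: np.ndarray,
                        outcome: np.ndarray) -> pd.DataFrame:
    """Rank-match CT and control records by predicted benefit.

    The excess records of the larger arm are dropped from the
    highest-predicted-benefit end of its sorted order.  Returns one row per
    matched pair with the pair predicted benefit and observed benefit.
    """
    pred = np.asarray(predicted_benefit, dtype=float)
    arm = np.asarray(arm)
    y = np.asarray(outcome).astype(float)
    ct = arm == "CT"
    ctrl = arm == "control"
    if ct.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both arms must be non-empty")
    ct_order = np.argsort(pred[ct], kind="stable")
    c_order = np.argsort(pred[ctrl], kind="stable")
    k = min(ct.sum(), ctrl.sum())
    ct_idx = np.flatnonzero(ct)[ct_order][:k]
    c_idx = np.flatnonzero(ctrl)[c_order][:k]
    return pd.DataFrame({
        "pred_pair": (pred[ct_idx] + pred[c_idx]) / 2.0,
        "obs_pair": y[c_idx] - y[ct_idx],
        "ct_index": ct_idx,
        "control_index": c_idx,
    })


def c_for_benefit(predicted_benefit: np.ndarray, arm: np.ndarray,
                  outcome: np.ndarray) -> tuple[float, int]:
    """Concordance between predicted and observed benefit over matched pairs.

    Returns ``(statistic, n_informative_pairs)`` where informative pairs of
    pairs are those with differing observed benefit; NaN if none exist.
    Invariant to strictly monotone transforms of the predictions.
    """
    pairs = match_benefit_pairs(predicted_benefit, arm, outcome)
    classes = [-1.0, 0.0, 1.0]
    num = 0.0
    den = 0
    for lo_i in range(len(classes)):
        for hi_i in range(lo_i + 1, len(classes)):
            hi = pairs.loc[pairs["obs_pair"] == classes[hi_i], "pred_pair"].to_numpy()
            lo = pairs.loc[pairs["obs_pair"] == classes[lo_i], "pred_pair"].to_numpy()
            s, n = _pairwise_auc(hi, lo)
            num += s
            den += n
    if den == 0:
        return float("nan"), 0
    return num / den, den


def _quantile_groups(pred: np.ndarray, n_groups: int) -> np.ndarray:
    """Deterministic quantile groups; ties broken by stable input order."""
    order = np.argsort(pred, kind="stable")
    groups = np.empty(len(pred), dtype=np.int32)
    splits = np.array_split(order, n_groups)
    for g, idx in enumerate(splits):
        groups[idx] = g
    return groups


def calibration_for_benefit(predicted_benefit: np.ndarray, arm: np.ndarray,
                            outcome: np.ndarray, n_groups: int = 5,
                            scale: str = "absolute") -> BenefitEvaluation:
    """Grouped calibration of predicted against observed benefit.

    Groups with a single-arm membership become NA rows and are excluded from
    the slope; if fewer than two informative groups remain (e.g. constant
    predictions), the slope and intercept are NA.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if scale not in ("absolute", "relative"):
        raise ValueError(f"unknown scale {scale!r}")
    from .rates import exact_rate_ratio

    pred = np.asarray(predicted_benefit, dtype=float)
    arm = np.asarray(arm)
    y = np.asarray(outcome).astype(float)
    if len(np.unique(pred)) < 2:
        groups = np.zeros(len(pred), dtype=np.int32)
        n_eff = 1
    else:
        groups = _quantile_groups(pred, n_groups)
        n_eff = n_groups
    rows = []
    notes = []
    for g in range(n_eff):
        m = groups == g
        ct = m & (arm == "CT")
        ctrl = m & (arm == "control")
        row = {"group": g, "n": int(m.sum()),
               "mean_predicted_benefit": float(pred[m].mean())}
        if ct.sum() == 0 or ctrl.sum() == 0:
            row["observed_benefit"] = np.nan
            notes.append(f"group {g} has a single-arm membership")
        elif scale == "absolute":
            row["observed_benefit"] = float(y[ctrl].mean() - y[ct].mean())
        else:
            comp = exact_rate_ratio(int(y[ct].sum()), float(ct.sum()),
                                    int(y[ctrl].sum()), float(ctrl.sum()))
            rr = comp.rate_ratio
            row["observed_benefit"] = 1.0 - rr if np.isfinite(rr) else np.nan
            row["ci_low"], row["ci_high"] = (1.0 - comp.rr_ci[1],
                                             1.0 - comp.rr_ci[0])
        rows.append(row)
    tab = pd.DataFrame(rows)
    ok = tab["observed_benefit"].notna()
    if ok.sum() >= 2 and tab.loc[ok, "mean_predicted_benefit"].nunique() >= 2:
        wtab = tab[ok]
        coeffs = np.polyfit(wtab["mean_predicted_benefit"],
                            wtab["observed_benefit"], 1, w=wtab["n"])
        slope, intercept = float(coeffs[0]), float(coeffs[1])
    else:
        slope, intercept = float("nan"), float("nan")
        notes.append("slope undefined (fewer than two informative groups)")
    return BenefitEvaluation(
        c_statistic=float("nan"), c_for_benefit=float("nan"), n_pairs=0,
        calibration_groups=tab, calibration_slope=slope,
        calibration_intercept=intercept, scale=scale, notes=notes)


# ---------------------------------------------------------------------------
# model evaluation / external validation
# ---------------------------------------------------------------------------

def _model_predictions(model, cohort: Cohort):
    """(predicted risk under assigned arm or None, predicted benefit p0-p1)."""
    df = cohort.records
    screen = (df["arm"] == "CT").to_numpy(bool)
    if hasattr(model, "predict_counterfactual"):
        p0, p1 = model.predict_counterfactual(df)
        risk = np.where(screen, p1, p0)
        return risk, p0 - p1
    # causal forest: benefit only
    from .forest import CausalForestModel, predict_cate

    if isinstance(model, CausalForestModel):
        tau = predict_cate(model, df).tau_hat
        return None, -tau
    raise TypeError(f"cannot evaluate model of type {type(model).__name__}")


@dataclass
class ValidationReport:
    development: str
    validation: str
    evaluation_absolute: BenefitEvaluation
    evaluation_relative: BenefitEvaluation
    estimates: list[EffectEstimate]


def evaluate_model(model, cohort: Cohort, outcome=None,
                   n_groups: int = 5) -> BenefitEvaluation:
    """C-statistic, C-for-benefit and absolute-scale calibration of a fitted
    model on one cohort."""
    from .pathmodels import _outcome_y

    outcome = outcome if outcome is not None else getattr(model, "outcome",
                                                          "overall_lcm")
    df = cohort.records
    y = _outcome_y(df, outcome)
    arm = df["arm"].to_numpy()
    risk, benefit = _model_predictions(model, cohort)
    cstat = c_statistic(risk, y) if risk is not None else float("nan")
    cfb, n_pairs = c_for_benefit(benefit, arm, y)
    cal = calibration_for_benefit(benefit, arm, y, n_groups=n_groups)
    return BenefitEvaluation(
        c_statistic=cstat, c_for_benefit=cfb, n_pairs=n_pairs,
        calibration_groups=cal.calibration_groups,
        calibration_slope=cal.calibration_slope,
        calibration_intercept=cal.calibration_intercept,
        scale="absolute", notes=cal.notes)


def external_validate(model, development: str, validation: Cohort,
                      outcome=None, n_groups: int = 5,
                      subgroups: Sequence = (None,)) -> ValidationReport:
    """Evaluate a frozen model on an external cohort (no recalibration).

    Raises if the validation cohort lacks a model covariate.  Standardized
    effectiveness estimates are recomputed on the validation cohort with the
    stored coefficients/trees (no bootstrap, point estimates only, since the
    model is frozen).
    """
    from .forest import CausalForestModel, forest_effectiveness
    from .pathmodels import _outcome_y, standardized_effectiveness

    missing = [c for c in getattr(model, "covariates", [])
               if c not in validation.records.columns
               and c not in ("sex", "smoking_status", "trial")]
    if missing:
        raise ValueError(f"validation cohort lacks covariates {missing}")
    outcome = outcome if outcome is not None else getattr(model, "outcome",
                                                          "overall_lcm")
    df = validation.records
    y = _outcome_y(df, outcome)
    arm = df["arm"].to_numpy()
    risk, benefit = _model_predictions(model, validation)
    cstat = c_statistic(risk, y) if risk is not None else float("nan")
    cfb, n_pairs = c_for_benefit(benefit, arm, y)
    cal_abs = calibration_for_benefit(benefit, arm, y, n_groups, "absolute")
    cal_rel = calibration_for_benefit(benefit, arm, y, n_groups, "relative")
    eval_abs = BenefitEvaluation(cstat, cfb, n_pairs, cal_abs.calibration_groups,
                                 cal_abs.calibration_slope,
                                 cal_abs.calibration_intercept, "absolute",
                                 cal_abs.notes)
    estimates = []
    for sg in subgroups:
        if isinstance(model, CausalForestModel):
            estimates.append(forest_effectiveness(model, validation, subgroup=sg))
        else:
            estimates.append(standardized_effectiveness(
                model, validation, subgroup=sg, B=0, outcome=outcome))
    return ValidationReport(development, validation.trial, eval_abs, cal_rel,
                            estimates)
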
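"""Published lung-cancer risk-prediction models and risk-quintile analyses.

Coefficient tables ship as versioned CSV resources with provenance headers
(``data/plcom2012.csv`` carries the published PLCOm2012 table; the LLP-form
table is a synthetic stand-in, clearly labelled as such in the resource).
On load, each table is validated against the model's expected term set and a
reference-profile identity (all covariates at their centering/reference
values must score exactly the inverse-logit of the intercept).

Quintile analyses split the cohort into five near-equal groups by a
deterministic stable sort on (score, id); within each quintile, relative
effectiveness comes from the exact rate-ratio machinery and absolute benefit
is the control-minus-CT cumulative mortality difference per 1000 randomized
participants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .rates import exact_rate_ratio

KNOWN_MODELS = ("PLCOm2012", "LLPv3-synthetic")

_RESOURCE = {"PLCOm2012": "plcom2012.csv",
             "LLPv3-synthetic": "llpv3_synthetic.csv"}

_EXPECTED_TERMS = {
    "PLCOm2012": {"intercept", "age", "race_ethnicity", "education", "bmi",
                  "copd", "personal_cancer_history", "family_lc_history",
                  "smoking_status", "smoking_intensity_inv", "years_smoked",
                  "years_quit"},
    "LLPv3-synthetic": {"intercept", "age", "sex", "smoking_duration_cat",
                        "pneumonia", "asbestos", "personal_cancer_history",
                        "family_lc_history"},
}


@dataclass(frozen=True)
class RiskScore:
    """A single participant's model-based baseline risk."""

    model: str
    horizon: float
    probability: float
    linear_predictor: float


@dataclass(frozen=True)
class QuintileEstimate:
    quintile: int
    n: int
    relative_effectiveness_pct: float
    rel_ci: tuple[float, float]
    absolute_benefit_per_1000: float
    abs_ci: tuple[float, float]
    n_events: int
    flagged: str | None = None


def load_coefficients(model: str) -> pd.DataFrame:
    """Load and validate a coefficient resource.

    Raises if the table's terms do not match the model's expected set or if
    the reference-profile identity fails.
    """
    if model not in _RESOURCE:
        raise ValueError(f"unknown risk model {model!r}; known: {KNOWN_MODELS}")
    ref = importlib.resources.files("screenhet.data") / _RESOURCE[model]
    with ref.open() as fh:
        tab = pd.read_csv(fh, comment="#", dtype={"level": str})
    terms = set(tab["term"])
    if terms != _EXPECTED_TERMS[model]:
        raise ValueError(f"coefficient table for {model} has unexpected terms: "
                         f"{sorted(terms ^ _EXPECTED_TERMS[model])}")
    return tab


def _coef(tab: pd.DataFrame, term: str, level: str | None = None) -> float:
    rows = tab[tab["term"] == term]
    if level is not None:
        rows = rows[rows["level"] == level]
    if len(rows) != 1:
        raise ValueError(f"term {term!r} level {level!r} not found uniquely")
    return float(rows["coefficient"].iloc[0])


def _centering(tab: pd.DataFrame, term: str) -> float:
    rows = tab[tab["term"] == term]
    c = rows["centering"].iloc[0]
    return float(c) if pd.notna(c) else 0.0


def _num(df: pd.DataFrame, col: str, default: float) -> np.ndarray:
    """Numeric column with the model's reference value for missing cells."""
    v = df[col].to_numpy(float) if col in df.columns else np.full(len(df), np.nan)
    return np.where(np.isnan(v), default, v)


def _flag(df: pd.DataFrame, col: str) -> np.ndarray:
    if col not in df.columns:
        return np.zeros(len(df))
    s = df[col]
    if s.dtype == "boolean":
        return s.fillna(False).to_numpy(float)
    return np.nan_to_num(s.to_numpy(float))


def _lp_plco(df: pd.DataFrame, tab: pd.DataFrame) -> np.ndarray:
    age = df["age"].to_numpy(float)
    if np.isnan(age).any():
        raise ValueError("PLCOm2012 scoring requires age for every record")
    cigs = df["cigs_per_day"].to_numpy(float)
    dur = df["years_smoked"].to_numpy(float)
    if np.isnan(cigs).any() or np.isnan(dur).any():
        raise ValueError("PLCOm2012 scoring requires cigs_per_day and "
                         "years_smoked for every record")
    lp = np.full(len(df), _coef(tab, "intercept"))
    lp += _coef(tab, "age") * (age - _centering(tab, "age"))
    race = df.get("race_ethnicity", pd.Series([None] * len(df))).astype(object)
    for lev in ("black", "hispanic", "asian"):
        lp += _coef(tab, "race_ethnicity", lev) * (race == lev).to_numpy(float)
    lp += _coef(tab, "education") * (
        _num(df, "education", _centering(tab, "education"))
        - _centering(tab, "education"))
    lp += _coef(tab, "bmi") * (_num(df, "bmi", _centering(tab, "bmi"))
                               - _centering(tab, "bmi"))
    lp += _coef(tab, "copd") * _flag(df, "copd")
    lp += _coef(tab, "personal_cancer_history") * _flag(df, "personal_cancer_history")
    lp += _coef(tab, "family_lc_history") * _flag(df, "family_lc_history")
    lp += _coef(tab, "smoking_status", "current") * (
        df["smoking_status"] == "current").to_numpy(float)
    centi = _centering(tab, "smoking_intensity_inv")
    lp += _coef(tab, "smoking_intensity_inv") * ((cigs / 10.0) ** -1 - centi)
    lp += _coef(tab, "years_smoked") * (dur - _centering(tab, "years_smoked"))
    lp += _coef(tab, "years_quit") * (
        _num(df, "years_quit", _centering(tab, "years_quit"))
        - _centering(tab, "years_quit"))
    return lp


def _lp_llp(df: pd.DataFrame, tab: pd.DataFrame) -> np.ndarray:
    age = df["age"].to_numpy(float)
    if np.isnan(age).any():
        raise ValueError("LLP-form scoring requires age for every record")
    lp = np.full(len(df), _coef(tab, "intercept"))
    lp += _coef(tab, "age") * (age - _centering(tab, "age"))
    lp += _coef(tab, "sex", "male") * (df["sex"] == "male").to_numpy(float)
    dur = _num(df, "years_smoked", 0.0)
    lp += np.where(
        dur <= 0, 0.0,
        np.where(dur <= 20, _coef(tab, "smoking_duration_cat", "1-20"),
                 np.where(dur <= 40, _coef(tab, "smoking_duration_cat", "21-40"),
                          _coef(tab, "smoking_duration_cat", ">40"))))
    # pneumonia and asbestos exposure are not collected in the cohort
    # schema; records score at the reference (absent)
    lp += _coef(tab, "pneumonia") * _flag(df, "pneumonia")
    lp += _coef(tab, "asbestos") * _flag(df, "asbestos")
    lp += _coef(tab, "personal_cancer_history") * _flag(df, "personal_cancer_history")
    lp += _coef(tab, "family_lc_history") * _flag(df, "family_lc_history")
    return lp


_HORIZON = {"PLCOm2012": 6.0, "LLPv3-synthetic": 5.0}


def score_cohort(cohort: Cohort | pd.DataFrame, model: str,
                 coefficients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score every record; returns a frame with ``linear_predictor`` and
    ``probability`` columns aligned with the cohort."""
    df = cohort.records if isinstance(cohort, Cohort) else cohort
    tab = coefficients if coefficients is not None else load_coefficients(model)
    if model == "PLCOm2012":
        lp = _lp_plco(df, tab)
    elif model == "LLPv3-synthetic":
        lp = _lp_llp(df, tab)
    else:
        raise ValueError(f"unknown risk model {model!r}")
    return pd.DataFrame({"linear_predictor": lp,
                         "probability": 1.0 / (1.0 + np.exp(-lp))},
                        index=df.index)


def score_risk_model(record: Mapping | pd.Series, model: str,
                     coefficients: pd.DataFrame | None = None) -> RiskScore:
    """Score one participant record (deterministic)."""
    df = pd.DataFrame([dict(record)])
    out = score_cohort(df, model, coefficients)
    return RiskScore(model=model, horizon=_HORIZON.get(model, np.nan),
                     probability=float(out["probability"].iloc[0]),
                     linear_predictor=float(out["linear_predictor"].iloc[0]))


# ---------------------------------------------------------------------------
# risk-quintile effectiveness
# ---------------------------------------------------------------------------

def assign_quintiles(scores: np.ndarray, ids: np.ndarray,
                     n_groups: int = 5) -> np.ndarray:
    """Deterministic near-equal-size groups by stable sort on (score, id)."""
    order = np.lexsort((np.asarray(ids, dtype=str), np.asarray(scores, float)))
    groups = np.empty(len(scores), dtype=np.int32)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = g + 1
    return groups


def effectiveness_by_risk_quintile(cohort: Cohort, scores: np.ndarray,
                                   alpha: float = 0.05,
                                   outcome="overall_lcm") -> pd.DataFrame:
    """Relative and absolute screening effectiveness by baseline-risk quintile.

    Relative effectiveness uses the exact rate-ratio machinery; absolute
    benefit is control-minus-CT cumulative mortality per 1000 randomized
    participants with a normal-approximation CI.  A quintile with single-arm
    membership yields a flagged NA row.
    """
    from .cohort import outcome_events_and_time

    df = cohort.records
    if len(scores) != len(df):
        raise ValueError("need one score per record")
    q = assign_quintiles(np.asarray(scores, float), df["id"].to_numpy(), 5)
    events, time = outcome_events_and_time(df, outcome)
    y = events.to_numpy(float)
    t = time.to_numpy(float)
    ct = (df["arm"] == "CT").to_numpy()
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for g in range(1, 6):
        m = q == g
        n_ct, n_c = int((m & ct).sum()), int((m & ~ct).sum())
        if n_ct == 0 or n_c == 0:
            rows.append(QuintileEstimate(g, int(m.sum()), np.nan,
                                         (np.nan, np.nan), np.nan,
                                         (np.nan, np.nan), 0,
                                         flagged="single-arm quintile"))
            continue
        e_ct, e_c = int(y[m & ct].sum()), int(y[m & ~ct].sum())
        comp = exact_rate_ratio(e_ct, float(t[m & ct].sum()),
                                e_c, float(t[m & ~ct].sum()), alpha)
        p1, p0 = e_ct / n_ct, e_c / n_c
        ab = 1000.0 * (p0 - p1)
        se = 1000.0 * np.sqrt(p1 * (1 - p1) / n_ct + p0 * (1 - p0) / n_c)
        rows.append(QuintileEstimate(
            g, int(m.sum()), comp.relative_effectiveness_pct,
            comp.effectiveness_ci_pct, ab, (ab - z * se, ab + z * se),
            e_ct + e_c, flagged=comp.flagged))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out
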
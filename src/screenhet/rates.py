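"""One-variable-at-a-time screening-effectiveness analyses.

Exact univariable rate-ratio tests based on the Poisson distribution, rate
differences per 1000 person-years, subgroup tables, stage-by-histology
incidence tables and histology-distribution tables.

The exact machinery conditions on the total event count: with events
``x1 ~ Poisson(r1 * py1)`` and ``x0 ~ Poisson(r0 * py0)`` and rate ratio
``RR = r1 / r0``, given the total ``T = x1 + x0`` the CT-arm count is
``Binomial(T, p)`` with ``p = RR*py1 / (RR*py1 + py0)``.  P-values and
confidence limits invert this binomial (Clopper-Pearson beta-quantile form)
and are mapped back to the rate-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HISTOLOGY_GROUPS, Cohort, outcome_events_and_time


@dataclass(frozen=True)
class RateComparison:
    """One CT-vs-control comparison cell.

    ``relative_effectiveness_pct`` is ``100 * (1 - rate_ratio)``: positive
    values are mortality (or incidence) reductions in the CT arm.
    """

    events_ct: int
    py_ct: float
    events_ctrl: int
    py_ctrl: float
    rate_ratio: float
    rr_ci: tuple[float, float]
    p_value: float
    rate_diff_per_1000: float
    rd_ci: tuple[float, float]
    relative_effectiveness_pct: float
    alpha: float = 0.05
    flagged: str | None = None

    @property
    def effectiveness_ci_pct(self) -> tuple[float, float]:
        """CI for the relative effectiveness (%), low to high."""
        lo, hi = self.rr_ci
        return (100.0 * (1.0 - hi), 100.0 * (1.0 - lo))


def _check_inputs(events_ct, py_ct, events_ctrl, py_ctrl) -> None:
    if events_ct < 0 or events_ctrl < 0:
        raise ValueError("event counts must be non-negative")
    if py_ct <= 0 or py_ctrl <= 0:
        raise ValueError("person-years must be positive in both arms")


def _binom_two_sided_p(x: int, n: int, p: float) -> float:
    """Two-sided exact p by the doubling convention min(1, 2*min(tails))."""
    lower = stats.binom.cdf(x, n, p)
    upper = stats.binom.sf(x - 1, n, p)
    return min(1.0, 2.0 * min(lower, upper))


def exact_rate_ratio(events_ct: int, py_ct: float, events_ctrl: int,
                     py_ctrl: float, alpha: float = 0.05) -> RateComparison:
    """Exact Poisson rate-ratio inference via the conditional binomial.

    Point estimate ``RR = (events_ct/py_ct) / (events_ctrl/py_ctrl)``;
    two-sided p-value for ``RR = 1`` and an exact ``1 - alpha`` CI from
    Clopper-Pearson limits on the conditional binomial proportion, mapped to
    the rate-ratio scale.  With zero events in the control arm only, the
    upper limit is infinite; with zero events in both arms the estimate is
    undefined and flagged with CI ``(0, inf)``.
    """
    _check_inputs(events_ct, py_ct, events_ctrl, py_ctrl)
    x, T = int(events_ct), int(events_ct) + int(events_ctrl)
    p_null = py_ct / (py_ct + py_ctrl)

    if T == 0:
        return RateComparison(x, py_ct, events_ctrl, py_ctrl, math.nan,
                              (0.0, math.inf), 1.0, 0.0,
                              _rate_diff_ci(0, py_ct, 0, py_ctrl, alpha),
                              math.nan, alpha, flagged="no events in either arm")

    if events_ctrl > 0:
        rr = (events_ct / py_ct) / (events_ctrl / py_ctrl)
    else:
        rr = math.inf
    p_value = _binom_two_sided_p(x, T, p_null)

    # Clopper-Pearson limits on p = RR*py1/(RR*py1+py0), beta-quantile form
    if x == 0:
        p_lo = 0.0
    else:
        p_lo = stats.beta.ppf(alpha / 2.0, x, T - x + 1)
    if x == T:
        p_hi = 1.0
    else:
        p_hi = stats.beta.ppf(1.0 - alpha / 2.0, x + 1, T - x)

    def to_rr(p: float) -> float:
        if p >= 1.0:
            return math.inf
        return (p / (1.0 - p)) * (py_ctrl / py_ct)

    rr_ci = (to_rr(p_lo), to_rr(p_hi))
    rd = 1000.0 * (events_ct / py_ct - events_ctrl / py_ctrl)
    rd_ci = _rate_diff_ci(events_ct, py_ct, events_ctrl, py_ctrl, alpha)
    rel = 100.0 * (1.0 - rr) if math.isfinite(rr) else -math.inf
    return RateComparison(x, py_ct, int(events_ctrl), py_ctrl, rr, rr_ci,
                          p_value, rd, rd_ci, rel, alpha)


def _rate_diff_ci(events_ct, py_ct, events_ctrl, py_ctrl,
                  alpha: float) -> tuple[float, float]:
    # independent Poisson variances on the rate scale; zero counts contribute
    # zero variance (no continuity correction)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rd = events_ct / py_ct - events_ctrl / py_ctrl
    se = math.sqrt(events_ct / py_ct ** 2 + events_ctrl / py_ctrl ** 2)
    return (1000.0 * (rd - z * se), 1000.0 * (rd + z * se))


def rate_difference(events_ct: int, py_ct: float, events_ctrl: int,
                    py_ctrl: float, alpha: float = 0.05) -> RateComparison:
    """Rate difference per 1000 person-years (CT minus control) with a
    normal-approximation CI from independent Poisson variances; the relative
    difference (percent of the control rate) is carried alongside."""
    _check_inputs(events_ct, py_ct, events_ctrl, py_ctrl)
    comp = exact_rate_ratio(events_ct, py_ct, events_ctrl, py_ctrl, alpha)
    flag = comp.flagged
    if events_ct == 0 or events_ctrl == 0:
        flag = flag or "zero event count: rate-difference variance is one-sided"
    return RateComparison(
        comp.events_ct, comp.py_ct, comp.events_ctrl, comp.py_ctrl,
        comp.rate_ratio, comp.rr_ci, comp.p_value, comp.rate_diff_per_1000,
        comp.rd_ci, comp.relative_effectiveness_pct, alpha, flagged=flag)


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def _arm_cell(df_py: pd.DataFrame) -> tuple[int, float, int, float]:
    by_arm = df_py.set_index("arm")
    e1 = int(by_arm.loc["CT", "events"]) if "CT" in by_arm.index else 0
    p1 = float(by_arm.loc["CT", "person_years"]) if "CT" in by_arm.index else 0.0
    e0 = int(by_arm.loc["control", "events"]) if "control" in by_arm.index else 0
    p0 = float(by_arm.loc["control", "person_years"]) if "control" in by_arm.index else 0.0
    return e1, p1, e0, p0


def _comparison_row(e1, p1, e0, p0, alpha, mode) -> RateComparison | None:
    if p1 <= 0 or p0 <= 0:
        return None
    fn = rate_difference if mode == "difference" else exact_rate_ratio
    return fn(e1, p1, e0, p0, alpha)


def subgroup_table(cohort: Cohort, variable: str,
                   outcome: str | tuple = "overall_lcm",
                   alpha: float = 0.05,
                   mode: str = "ratio") -> pd.DataFrame:
    """One :class:`RateComparison` per level of a categorized variable.

    For histology-specific outcomes, deaths from other histologies are
    non-events.  Levels with a single-arm membership (or no person-time) are
    reported as flagged NA rows.  Returns a tidy frame with the comparison
    object in the ``comparison`` column plus flattened estimate columns.
    """
    from .cohort import person_years  # local to avoid cycle at import time

    tab = person_years(cohort, by=[variable], outcome=outcome)
    rows = []
    for level, cell in tab.groupby(variable, dropna=False, observed=True):
        comp = _comparison_row(*_arm_cell(cell), alpha, mode)
        rows.append(_tidy_row(cohort.trial, outcome, variable, level, comp))
    return pd.DataFrame(rows)


def overall_table(cohort: Cohort, outcome: str | tuple = "overall_lcm",
                  alpha: float = 0.05, mode: str = "ratio") -> pd.DataFrame:
    """Single-row table for the whole cohort (no subgrouping)."""
    from .cohort import person_years

    tab = person_years(cohort, by=None, outcome=outcome)
    comp = _comparison_row(*_arm_cell(tab), alpha, mode)
    return pd.DataFrame([_tidy_row(cohort.trial, outcome, "overall", "all", comp)])


def _outcome_label(outcome) -> str:
    if isinstance(outcome, tuple):
        return ":".join(str(x) for x in outcome)
    return str(outcome)


def _tidy_row(trial, outcome, variable, level, comp: RateComparison | None) -> dict:
    row = {
        "trial": trial, "method": "rate_ratio",
        "outcome": _outcome_label(outcome),
        "subgroup_var": variable, "subgroup_level": level,
    }
    if comp is None:
        row.update(estimate_pct=np.nan, ci_low=np.nan, ci_high=np.nan,
                   p_value=np.nan, rate_diff_per_1000=np.nan,
                   rd_ci_low=np.nan, rd_ci_high=np.nan,
                   events_ct=0, py_ct=0.0, events_ctrl=0, py_ctrl=0.0,
                   flagged="empty or single-arm level", comparison=None)
        return row
    lo, hi = comp.effectiveness_ci_pct
    row.update(estimate_pct=comp.relative_effectiveness_pct,
               ci_low=lo, ci_high=hi, p_value=comp.p_value,
               rate_diff_per_1000=comp.rate_diff_per_1000,
               rd_ci_low=comp.rd_ci[0], rd_ci_high=comp.rd_ci[1],
               events_ct=comp.events_ct, py_ct=comp.py_ct,
               events_ctrl=comp.events_ctrl, py_ctrl=comp.py_ctrl,
               flagged=comp.flagged, comparison=comp)
    return row


def stage_histology_table(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Incidence-rate differences per 1000 person-years by histology and
    stage group (early/late), plus an all-stage row per histology."""
    rows = []
    for h in HISTOLOGY_GROUPS:
        for stage in ("early", "late", "all"):
            outcome = ("incidence", h) if stage == "all" else ("incidence", h, stage)
            tab = overall_table(cohort, outcome=outcome, alpha=alpha,
                                mode="difference")
            row = tab.iloc[0].to_dict()
            row.update(histology=h, stage=stage)
            rows.append(row)
    return pd.DataFrame(rows)


def histology_distribution(cohort: Cohort, factor: str | None = None,
                           arm: str = "both") -> pd.DataFrame:
    """Histology proportions over the four groups among lung-cancer cases,
    per level of ``factor`` (or one overall row); rows sum to 1.

    ``arm`` restricts to ``"CT"``, ``"control"`` or ``"both"`` arms.  Levels
    with no cases yield NA rows.  NOS cases are excluded from the
    denominator (they carry no resolved group).
    """
    df = cohort.records
    if arm != "both":
        df = df[df["arm"] == arm]
    cases = df[df["lc_diagnosis"].fillna(False).astype(bool)
               & df["histology"].isin(HISTOLOGY_GROUPS)]
    if factor is None:
        groups = [("all", cases)]
    else:
        if factor not in df.columns:
            raise ValueError(f"factor {factor!r} not in cohort")
        groups = list(cases.groupby(factor, observed=True))
    rows = []
    for level, sub in groups:
        counts = sub["histology"].value_counts()
        total = int(counts.sum())
        row = {"level": level, "n_cases": total}
        for h in HISTOLOGY_GROUPS:
            row[h] = counts.get(h, 0) / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional post-processing for
    subgroup panels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
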
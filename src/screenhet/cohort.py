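"""Person-level two-arm screening-trial cohorts.

A :class:`Cohort` wraps a pandas DataFrame with one row per randomized
participant, carrying harmonized baseline risk factors (age, sex, smoking
history, comorbidity flags), follow-up, and lung-cancer outcomes (diagnosis,
histology group, stage group, detection mode, lung-cancer death).  The schema
is the single interchange format of the package: simulated trials, eligibility
filtering, follow-up equalization, person-years accounting and every
downstream estimator all operate on it.

Conventions
-----------
* Arms are ``"CT"`` (low-dose CT screening) and ``"control"``.
* Histology groups are ``ADN`` (adenocarcinoma), ``SQM`` (squamous-cell
  carcinoma), ``OTH`` (other lung cancers) and ``SCLC`` (small-cell
  carcinoma); ``NOS`` marks non-small-cell cancers not otherwise specified,
  a pre-analysis state resolved by imputation or mapped to ``OTH``.
* Stage groups are ``early`` (I-II) and ``late`` (III-IV).
* Missing values are empty fields in CSV and NaN/NA in memory.
* Person-time for lung-cancer deaths ends at ``lc_death_time``; all other
  records contribute ``followup_years``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "screenhet-cohort-v1"

ARMS = ("CT", "control")
SEXES = ("female", "male", "unknown")
SMOKING_STATUS = ("current", "former", "never")
HISTOLOGY_GROUPS = ("ADN", "SQM", "OTH", "SCLC")
HISTOLOGY_STATES = HISTOLOGY_GROUPS + ("NOS", "none")
STAGE_GROUPS = ("early", "late", "unknown", "none")
DETECTION_MODES = ("screen", "clinical", "none")

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "arm": ARMS,
    "sex": SEXES,
    "smoking_status": SMOKING_STATUS,
    "histology": HISTOLOGY_STATES,
    "stage_group": STAGE_GROUPS,
    "detection_mode": DETECTION_MODES,
}

NUMERIC_COLUMNS = (
    "age", "education", "bmi", "cigs_per_day", "years_smoked", "pack_years",
    "years_quit", "followup_years", "lc_diagnosis_time", "lc_death_time",
)
FLAG_COLUMNS = (
    "copd", "emphysema", "personal_cancer_history", "family_lc_history",
    "lc_diagnosis", "lc_death",
)
STRING_COLUMNS = ("id", "trial", "race_ethnicity", "center")

COLUMN_ORDER = (
    "id", "trial", "arm", "center", "age", "sex", "race_ethnicity",
    "education", "bmi", "smoking_status", "cigs_per_day", "years_smoked",
    "pack_years", "years_quit", "copd", "emphysema",
    "personal_cancer_history", "family_lc_history", "followup_years",
    "lc_diagnosis", "lc_diagnosis_time", "histology", "stage_group",
    "detection_mode", "lc_death", "lc_death_time",
)

MANDATORY_COLUMNS = (
    "id", "arm", "age", "sex", "smoking_status", "pack_years", "years_quit",
    "followup_years", "lc_diagnosis", "lc_death",
)

#: absolute slack allowed between pack_years and cigs_per_day*years_smoked/20
PACK_YEAR_TOLERANCE = 2.0
_TIME_EPS = 1e-9


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class CohortError(ValueError):
    """Cohort-level invariant violation (duplicate ids, empty arm, ...)."""


@dataclass(frozen=True)
class RowIssue:
    """Row-level diagnostic emitted when a record violates an invariant."""

    row_id: str
    field: str
    message: str


@dataclass(frozen=True)
class ExclusionLog:
    """One applied eligibility rule and the ids it removed."""

    rule: str
    n_removed: int
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_removed != len(self.ids):
            raise ValueError("n_removed must equal |ids|")


@dataclass
class Cohort:
    """A validated participant table for one trial.

    Parameters
    ----------
    records
        One row per participant, columns from :data:`COLUMN_ORDER`.
    trial
        Trial label, e.g. ``"NELSON"``, ``"NLST"`` or ``"SYNTH"``.
    followup_cap
        Analysis follow-up window in years since randomization
        (NELSON-like 10, NLST-like 7).
    """

    records: pd.DataFrame
    trial: str = "SYNTH"
    followup_cap: float = 10.0
    rejected: list[RowIssue] = field(default_factory=list, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def arm_counts(self) -> dict[str, int]:
        counts = self.records["arm"].value_counts()
        return {arm: int(counts.get(arm, 0)) for arm in ARMS}

    def copy(self) -> "Cohort":
        return Cohort(self.records.copy(), self.trial, self.followup_cap)

    def validate(self) -> None:
        """Raise :class:`CohortError` on cohort-level violations and
        :class:`CohortError` listing row issues if any record invariant fails."""
        df = self.records
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
            raise CohortError(f"duplicate participant ids, e.g. {dups}")
        counts = self.arm_counts
        if min(counts.values()) == 0:
            raise CohortError(f"both arms must be non-empty, got {counts}")
        issues = validate_records(df)
        if issues:
            head = "; ".join(f"{i.row_id}:{i.field}:{i.message}" for i in issues[:5])
            raise CohortError(f"{len(issues)} record invariant violations: {head}")


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in COLUMN_ORDER:
        if col not in df.columns:
            df[col] = np.nan
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in FLAG_COLUMNS:
        s = df[col]
        if s.dtype == object:
            lut = {"1": True, "0": False, "True": True, "False": False,
                   "true": True, "false": False, "": pd.NA,
                   "1.0": True, "0.0": False}
            s = s.map(lambda v: lut.get(v, v) if isinstance(v, str) else v)
        df[col] = s.astype("boolean")
    for col in STRING_COLUMNS:
        df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    for col in CATEGORY_LEVELS:
        df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    df["id"] = df["id"].astype(str)
    # unrecorded outcome states default to "none" (validation then flags
    # diagnosed cases that lost their histology)
    for col in ("histology", "stage_group", "detection_mode"):
        df[col] = df[col].where(df[col].notna(), "none")
    return df[list(COLUMN_ORDER)]


def validate_records(df: pd.DataFrame) -> list[RowIssue]:
    """Vectorized record-invariant checks; returns one issue per violation."""
    issues: list[RowIssue] = []
    ids = df["id"].astype(str)

    def flag(mask: pd.Series, col: str, msg: str) -> None:
        for rid in ids[mask.fillna(False).astype(bool)]:
            issues.append(RowIssue(rid, col, msg))

    for col in MANDATORY_COLUMNS:
        flag(df[col].isna(), col, "mandatory value missing")
    for col, levels in CATEGORY_LEVELS.items():
        flag(df[col].notna() & ~df[col].isin(levels), col,
             f"value not in {levels}")

    dx = df["lc_diagnosis"].fillna(False).astype(bool)
    death = df["lc_death"].fillna(False).astype(bool)
    flag(death & ~dx, "lc_death", "lc_death without lc_diagnosis")
    flag(dx & (df["histology"] == "none"), "histology",
         "diagnosed case without histology state")
    flag(~dx & df["histology"].isin(HISTOLOGY_GROUPS + ("NOS",)), "histology",
         "histology recorded without diagnosis")
    fup = df["followup_years"]
    for tcol in ("lc_diagnosis_time", "lc_death_time"):
        flag(df[tcol].notna() & (df[tcol] > fup + _TIME_EPS), tcol,
             "event time exceeds followup_years")
    flag(death & df["lc_death_time"].isna(), "lc_death_time",
         "lc_death without lc_death_time")

    cur = df["smoking_status"] == "current"
    former = df["smoking_status"] == "former"
    yq = df["years_quit"]
    flag(cur & yq.notna() & (yq > _TIME_EPS), "years_quit",
         "current smoker with years_quit > 0")
    flag(former & yq.notna() & (yq <= _TIME_EPS), "years_quit",
         "former smoker with years_quit = 0")

    have = df["cigs_per_day"].notna() & df["years_smoked"].notna() & df["pack_years"].notna()
    implied = df["cigs_per_day"] * df["years_smoked"] / 20.0
    flag(have & ((df["pack_years"] - implied).abs() > PACK_YEAR_TOLERANCE),
         "pack_years", "pack_years inconsistent with cigs_per_day*years_smoked/20")
    return issues


def load_cohort(
    path: str | Path | io.IOBase,
    schema: Mapping[str, str] | None = None,
    trial: str | None = None,
    followup_cap: float | None = None,
) -> Cohort:
    """Read a cohort CSV, validate it, and reject invalid rows.

    Parameters
    ----------
    path
        Delimited text file in the cohort schema (leading ``#`` comment lines
        carry the schema version and are ignored).
    schema
        Optional mapping ``{file column -> schema column}`` applied before
        validation.
    trial, followup_cap
        Override the trial label / follow-up window; by default the modal
        ``trial`` value and the maximum observed follow-up (rounded up) are
        used.

    Rows violating record invariants are dropped and reported on the returned
    cohort's ``rejected`` attribute as :class:`RowIssue` diagnostics.

    Raises
    ------
    SchemaError
        If a mandatory column cannot be mapped.
    """
    raw = pd.read_csv(path, comment="#", dtype=object)
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory columns missing from file: {missing}")
    df = _coerce_types(raw)
    issues = validate_records(df)
    bad_ids = {i.row_id for i in issues}
    kept = df[~df["id"].isin(bad_ids)].reset_index(drop=True)
    if trial is None:
        vals = kept["trial"].dropna()
        trial = str(vals.mode().iloc[0]) if len(vals) else "SYNTH"
    if followup_cap is None:
        followup_cap = float(np.ceil(kept["followup_years"].max())) if len(kept) else 10.0
    cohort = Cohort(kept, trial=trial, followup_cap=followup_cap)
    cohort.rejected = issues
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV (versioned comment header, empty fields for NA)."""
    df = cohort.records.copy()
    for col in FLAG_COLUMNS:
        df[col] = df[col].map({True: 1, False: 0}, na_action="ignore")
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} trial={cohort.trial} "
                 f"followup_cap={cohort.followup_cap}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# eligibility filtering
# ---------------------------------------------------------------------------

def _rule_never_smoker(df: pd.DataFrame) -> pd.Series:
    return ~df["smoking_status"].isin(("current", "former"))


def _rule_prior_lc(df: pd.DataFrame) -> pd.Series:
    # diagnosis before randomization is encoded as a negative diagnosis time
    return df["lc_diagnosis"].fillna(False).astype(bool) & (
        df["lc_diagnosis_time"] < 0)


def _rule_missing_incidence_date(df: pd.DataFrame) -> pd.Series:
    return df["lc_diagnosis"].fillna(False).astype(bool) & df["lc_diagnosis_time"].isna()


BUILTIN_RULES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "never_smoker": _rule_never_smoker,
    "prior_lc": _rule_prior_lc,
    "missing_incidence_date": _rule_missing_incidence_date,
}

RuleSpec = "str | tuple[str, Callable[[pd.DataFrame], pd.Series]]"


def apply_eligibility_filters(
    cohort: Cohort,
    rules: Sequence[str | tuple[str, Callable[[pd.DataFrame], pd.Series]]],
) -> tuple[Cohort, list[ExclusionLog]]:
    """Apply ordered exclusion rules; returns the filtered cohort and one
    :class:`ExclusionLog` per rule in application order.

    Built-in rules: ``never_smoker``, ``prior_lc`` (diagnosis before
    randomization, negative diagnosis time), ``missing_incidence_date``.
    A custom rule is a ``(label, predicate)`` pair where the predicate maps
    the record table to a boolean mask of rows to *remove*.  Filters are
    idempotent: re-applying a rule removes nothing.
    """
    df = cohort.records
    logs: list[ExclusionLog] = []
    for rule in rules:
        if isinstance(rule, str):
            if rule not in BUILTIN_RULES:
                raise ValueError(
                    f"unknown eligibility rule {rule!r}; "
                    f"known rules: {sorted(BUILTIN_RULES)}")
            name, pred = rule, BUILTIN_RULES[rule]
        else:
            name, pred = rule
        mask = pred(df).fillna(False).astype(bool)
        removed = tuple(df.loc[mask, "id"])
        logs.append(ExclusionLog(name, len(removed), removed))
        df = df[~mask]
    out = Cohort(df.reset_index(drop=True), cohort.trial, cohort.followup_cap)
    return out, logs


def write_exclusion_log(logs: Sequence[ExclusionLog], path: str | Path) -> None:
    pd.DataFrame({"rule": [l.rule for l in logs],
                  "n_removed": [l.n_removed for l in logs]}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# follow-up equalization
# ---------------------------------------------------------------------------

def truncate_follow_up(cohort: Cohort, cap: float) -> Cohort:
    """Equalize follow-up at ``cap`` years since randomization.

    Follow-up is clipped at the cap; any diagnosis or death occurring after
    the cap is reset to a non-event (histology, stage and detection mode
    cleared for diagnoses beyond the cap).  Truncation never creates events,
    so event totals are monotone non-increasing in the cap.
    """
    if not cap > 0:
        raise ValueError(f"cap must be positive, got {cap}")
    df = cohort.records.copy()
    late_death = df["lc_death_time"].notna() & (df["lc_death_time"] > cap + _TIME_EPS)
    df.loc[late_death, "lc_death"] = False
    df.loc[late_death, "lc_death_time"] = np.nan
    late_dx = df["lc_diagnosis_time"].notna() & (df["lc_diagnosis_time"] > cap + _TIME_EPS)
    df.loc[late_dx, "lc_diagnosis"] = False
    df.loc[late_dx, "lc_diagnosis_time"] = np.nan
    df.loc[late_dx, ["histology", "stage_group", "detection_mode"]] = "none"
    # a death whose diagnosis survived truncation but whose death time did not
    # leaves the diagnosis intact (the case remains incident within the window)
    df["followup_years"] = df["followup_years"].clip(upper=cap)
    return Cohort(df, cohort.trial, followup_cap=min(cohort.followup_cap, cap))


# ---------------------------------------------------------------------------
# outcomes and person-years
# ---------------------------------------------------------------------------

def outcome_events_and_time(
    df: pd.DataFrame,
    outcome: str | tuple,
) -> tuple[pd.Series, pd.Series]:
    """Resolve an outcome definition to (event indicator, person-time).

    Outcome definitions:

    * ``"overall_lcm"`` / ``"lc_death"`` -- death from lung cancer; deaths
      contribute person-time to ``lc_death_time``, all others to
      ``followup_years``.
    * ``("lcm", histology)`` -- death from lung cancer of one histology group;
      deaths from other histologies are non-events (not competing-risk
      censored) but still stop contributing person-time at death.
    * ``"lc_incidence"`` -- lung-cancer diagnosis; cases contribute
      person-time to diagnosis.
    * ``("incidence", histology)`` and ``("incidence", histology, stage)`` --
      histology-specific (optionally stage-specific) incidence.
    """
    death = df["lc_death"].fillna(False).astype(bool)
    dx = df["lc_diagnosis"].fillna(False).astype(bool)
    mortality_time = df["followup_years"].where(~death, df["lc_death_time"])
    incidence_time = df["followup_years"].where(~dx, df["lc_diagnosis_time"])
    if outcome in ("overall_lcm", "lc_death"):
        return death, mortality_time
    if outcome == "lc_incidence":
        return dx, incidence_time
    if isinstance(outcome, tuple):
        kind = outcome[0]
        if kind == "lcm":
            return death & (df["histology"] == outcome[1]), mortality_time
        if kind == "incidence":
            ev = dx & (df["histology"] == outcome[1])
            if len(outcome) > 2:
                ev &= df["stage_group"] == outcome[2]
            return ev, incidence_time
    raise ValueError(f"unknown outcome definition {outcome!r}")


def person_years(
    cohort: Cohort,
    by: Sequence[str] | None = None,
    outcome: str | tuple = "overall_lcm",
) -> pd.DataFrame:
    """Events and person-years per (group, arm) cell.

    ``by`` names grouping columns (beyond arm); cells with zero person-time
    are reported with ``events = 0``.  Output is additive over any disjoint
    partition of the cohort.
    """
    df = cohort.records
    by = list(by or [])
    for var in by:
        if var not in df.columns:
            raise ValueError(f"grouping variable {var!r} not in cohort")
    if df["followup_years"].isna().any():
        raise ValueError("followup_years missing for some records")
    events, time = outcome_events_and_time(df, outcome)
    tab = pd.DataFrame({"events": events.astype(int), "person_years": time})
    keys = [df[v] for v in by] + [df["arm"]]
    grouped = tab.groupby(keys, dropna=False, observed=True).sum().reset_index()
    grouped.columns = by + ["arm", "events", "person_years"]
    return grouped


# ---------------------------------------------------------------------------
# covariate categorization
# ---------------------------------------------------------------------------

def _default_labels(cuts: Sequence[float]) -> list[str]:
    # mirrors printed subgroup labels: "<30", "30-39", "40-49", ">50"
    labels = [f"<{cuts[0]:g}"]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        upper = hi - 1 if float(hi).is_integer() and float(lo).is_integer() else hi
        labels.append(f"{lo:g}–{upper:g}")
    labels.append(f">{cuts[-1]:g}")
    return labels


def categorize_covariates(
    cohort: Cohort,
    breaks: Mapping[str, Sequence[float] | tuple[Sequence[float], Sequence[str]]],
) -> Cohort:
    """Add categorical ``<var>_group`` columns from cut points.

    Intervals are left-closed/right-open except the last, which is closed
    above; a value exactly at the first cut therefore lands in the second
    group.  Cut points must be strictly increasing.  Original columns are
    retained.
    """
    df = cohort.records.copy()
    for var, spec in breaks.items():
        if isinstance(spec, tuple) and len(spec) == 2 and not np.isscalar(spec[0]):
            cuts, labels = list(spec[0]), list(spec[1])
        else:
            cuts, labels = list(spec), None
        if any(b >= a for b, a in zip(cuts, cuts[1:])) or len(cuts) == 0:
            raise ValueError(f"cut points for {var!r} must be strictly increasing")
        if labels is None:
            labels = _default_labels(cuts)
        if len(labels) != len(cuts) + 1:
            raise ValueError(f"{var!r}: need {len(cuts) + 1} labels, got {len(labels)}")
        if var not in df.columns:
            raise ValueError(f"variable {var!r} not in cohort")
        values = df[var].to_numpy(dtype=float)
        idx = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
        out = np.array([None] * len(df), dtype=object)
        ok = ~np.isnan(values)
        out[ok] = np.asarray(labels, dtype=object)[idx[ok]]
        df[f"{var}_group"] = out
    return Cohort(df, cohort.trial, cohort.followup_cap)
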
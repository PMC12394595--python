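"""k-nearest-neighbour multiple imputation, Rubin pooling and the
histology-reassignment sensitivity analysis.

Missing covariates are imputed from the ``k`` nearest complete donors under a
Gower-style distance (range-standardized numeric variables plus simple
matching on categoricals), computed over the variables each incomplete
record has observed.  All candidate predictors, including the lung-cancer
mortality outcome, participate in the distance; the outcome itself is never
imputed.  The deterministic single imputation aggregates donors (numeric
median, categorical majority with a seeded tie-break); multiple imputation
propagates uncertainty by sampling one donor uniformly from the k nearest
for each missing cell, independently per replicate.

Replicate estimates are combined by Rubin's rules: pooled point is the mean,
total variance ``T = W + (1 + 1/m) B`` with within-variance ``W`` and
between-variance ``B``, and a Barnard-Rubin adjusted t reference for the
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, HISTOLOGY_GROUPS

#: variables participating in the imputation distance by default
NUMERIC_PREDICTORS = ("age", "education", "bmi", "cigs_per_day",
                      "years_smoked", "pack_years", "years_quit")
CATEGORICAL_PREDICTORS = ("sex", "smoking_status", "race_ethnicity", "copd",
                          "emphysema", "personal_cancer_history",
                          "family_lc_history", "lc_death")
#: columns that may never be imputed (the outcome enters as predictor only)
NEVER_IMPUTED = ("lc_death", "lc_diagnosis", "followup_years", "arm", "id")


@dataclass
class ImputationSet:
    """m completed cohorts plus the metadata needed for pooling."""

    m: int
    completed_cohorts: list[Cohort]
    k_neighbours: int
    seeds: list[int]
    variables_imputed: list[str]

    def __post_init__(self) -> None:
        if not (self.m == len(self.completed_cohorts) == len(self.seeds)):
            raise ValueError("m, cohorts and seeds must align")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m replicate estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]
    m: int


def _imputable_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in NUMERIC_PREDICTORS + CATEGORICAL_PREDICTORS
            if c in df.columns and c not in NEVER_IMPUTED]
    return [c for c in cols if df[c].isna().any()]


def _distance_matrix(target: pd.DataFrame, donors: pd.DataFrame,
                     ranges: dict[str, float]) -> np.ndarray:
    """Gower distances (rows of ``target``) x (rows of ``donors``) over the
    target's observed variables."""
    n_t, n_d = len(target), len(donors)
    dist = np.zeros((n_t, n_d))
    weight = np.zeros((n_t, 1))
    for col in NUMERIC_PREDICTORS:
        if col not in target.columns:
            continue
        tv = target[col].to_numpy(float)[:, None]
        dv = donors[col].to_numpy(float)[None, :]
        ok = ~np.isnan(tv)
        rng = ranges.get(col, 1.0) or 1.0
        dist += np.where(ok, np.abs(tv - dv) / rng, 0.0)
        weight += ok
    for col in CATEGORICAL_PREDICTORS:
        if col not in target.columns:
            continue
        # object arrays with plain nan markers: pd.NA breaks elementwise !=
        tv = target[col].astype(object).where(target[col].notna(), np.nan
                                              ).to_numpy()[:, None]
        dv = donors[col].astype(object).where(donors[col].notna(), np.nan
                                              ).to_numpy()[None, :]
        ok = ~pd.isna(tv)
        dist += np.where(ok, (tv != dv).astype(float), 0.0)
        weight += ok
    return dist / np.maximum(weight, 1.0)


def _neighbour_table(cohort: Cohort, k: int):
    """Incomplete-row indices, their k nearest donor row indices, and the
    list of imputed variables."""
    df = cohort.records
    variables = _imputable_columns(df)
    if not variables:
        return np.array([], dtype=int), np.empty((0, k), dtype=int), variables
    pred_cols = [c for c in NUMERIC_PREDICTORS + CATEGORICAL_PREDICTORS
                 if c in df.columns]
    incomplete = df[variables].isna().any(axis=1).to_numpy()
    donors_ok = df[pred_cols].notna().all(axis=1).to_numpy()
    donor_idx = np.flatnonzero(donors_ok)
    target_idx = np.flatnonzero(incomplete)
    if len(donor_idx) == 0:
        raise ValueError("no complete donor records available")
    kk = min(k, len(donor_idx))
    if kk < k:
        import warnings
        warnings.warn(f"only {kk} complete donors available (requested k={k})")
    ranges = {c: float(np.nanmax(df[c].to_numpy(float))
                       - np.nanmin(df[c].to_numpy(float)))
              for c in NUMERIC_PREDICTORS if c in df.columns}
    neigh = np.empty((len(target_idx), kk), dtype=int)
    chunk = max(1, int(2e6 // max(len(donor_idx), 1)))
    donors = df.iloc[donor_idx]
    for lo in range(0, len(target_idx), chunk):
        hi = min(lo + chunk, len(target_idx))
        dmat = _distance_matrix(df.iloc[target_idx[lo:hi]], donors, ranges)
        part = np.argpartition(dmat, kk - 1, axis=1)[:, :kk]
        # order the k nearest by distance for deterministic aggregation
        row = np.arange(hi - lo)[:, None]
        order = np.argsort(dmat[row, part], axis=1, kind="stable")
        neigh[lo:hi] = donor_idx[part[row, order]]
    return target_idx, neigh, variables


def knn_impute(cohort: Cohort, k: int = 5, seed: int = 0) -> Cohort:
    """Deterministic single kNN imputation.

    Numeric cells take the median of the k nearest donors, categorical cells
    the majority value (ties broken by the seeded generator).  A cohort with
    no missing values is returned unchanged (copy).
    """
    df = cohort.records.copy()
    target_idx, neigh, variables = _neighbour_table(cohort, k)
    if not len(target_idx):
        return Cohort(df, cohort.trial, cohort.followup_cap)
    rng = np.random.default_rng(seed)
    for col in variables:
        vals = df[col].to_numpy()
        missing_rows = np.flatnonzero(pd.isna(df[col].to_numpy()))
        pos = {int(t): i for i, t in enumerate(target_idx)}
        for r in missing_rows:
            donors = neigh[pos[int(r)]]
            dv = df[col].to_numpy()[donors]
            if col in NUMERIC_PREDICTORS:
                vals[r] = float(np.median(dv.astype(float)))
            else:
                uniq, counts = np.unique(dv.astype(str), return_counts=True)
                best = uniq[counts == counts.max()]
                choice = best[0] if len(best) == 1 else rng.choice(best)
                vals[r] = _cast_back(df[col], choice)
        df[col] = _assign(df[col], vals)
    return Cohort(df, cohort.trial, cohort.followup_cap)


def _cast_back(series: pd.Series, value):
    if series.dtype == "boolean":
        return value in ("True", "1", "true", True, 1)
    return value


def _assign(series: pd.Series, values: np.ndarray) -> pd.Series:
    return pd.Series(values, index=series.index).astype(series.dtype)


def multiply_impute(cohort: Cohort, m: int = 30, k: int = 5,
                    master_seed: int = 0) -> ImputationSet:
    """m stochastic kNN imputations with per-replicate seeds.

    Each missing cell draws one donor uniformly from the k nearest;
    ``m = 1`` falls back to the deterministic aggregation of
    :func:`knn_impute`.  Deterministic given ``master_seed``.
    """
    target_idx, neigh, variables = _neighbour_table(cohort, k)
    seeds = [int(s) for s in
             np.random.SeedSequence(master_seed).generate_state(max(m, 1))
             % (2 ** 31)]
    if m == 1:
        return ImputationSet(1, [knn_impute(cohort, k, seeds[0])], k, seeds[:1],
                             variables)
    completed = []
    base = cohort.records
    for rep in range(m):
        rng = np.random.default_rng(seeds[rep])
        df = base.copy()
        for col in variables:
            vals = df[col].to_numpy()
            col_vals = base[col].to_numpy()
            missing_rows = np.flatnonzero(pd.isna(col_vals))
            pos = {int(t): i for i, t in enumerate(target_idx)}
            for r in missing_rows:
                donors = neigh[pos[int(r)]]
                pick = donors[rng.integers(len(donors))]
                vals[r] = col_vals[pick]
            df[col] = _assign(df[col], vals)
        completed.append(Cohort(df, cohort.trial, cohort.followup_cap))
    return ImputationSet(m, completed, k, seeds[:m], variables)


def rubin_pool(estimates: Sequence[tuple[float, float]], m: int | None = None,
               alpha: float = 0.05, df_com: float | None = None) -> PooledEstimate:
    """Rubin's rules for m replicate (point, variance) pairs.

    ``T = W + (1 + 1/m) B``; interval from a t reference with the
    Barnard-Rubin adjusted degrees of freedom (falling back to the classical
    large-sample form when ``df_com`` is not given).  ``m = 1`` passes the
    single estimate through with a normal interval.
    """
    pts = np.array([e[0] for e in estimates], dtype=float)
    vrs = np.array([e[1] for e in estimates], dtype=float)
    if m is None:
        m = len(pts)
    if len(pts) != m or len(vrs) != m:
        raise ValueError("length of estimates does not match m")
    if m < 1:
        raise ValueError("need at least one estimate")
    q = float(pts.mean())
    w = float(vrs.mean())
    if m == 1:
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(w)
        return PooledEstimate(q, w, 0.0, w, float("inf"), (q - half, q + half), 1)
    b = float(pts.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b <= 0:
        dof = float("inf")
    else:
        r = (1.0 + 1.0 / m) * b / w if w > 0 else float("inf")
        dof = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else float(m - 1)
        if df_com is not None:
            lam = (1.0 + 1.0 / m) * b / t
            dof_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            dof = 1.0 / (1.0 / dof + 1.0 / dof_obs)
    half = (stats.t.ppf(1 - alpha / 2, dof) if np.isfinite(dof)
            else stats.norm.ppf(1 - alpha / 2)) * np.sqrt(t)
    return PooledEstimate(q, w, b, t, dof, (q - half, q + half), m)


# ---------------------------------------------------------------------------
# NOS histology reassignment (sensitivity analysis)
# ---------------------------------------------------------------------------

NSCLC_GROUPS = ("ADN", "SQM", "OTH")


def reassign_nos_histology(cohort: Cohort, m: int = 30, seed: int = 0) -> ImputationSet:
    """Reassign NOS-coded non-small-cell cases to {ADN, SQM, OTH}.

    A multinomial logistic model is fit on cases with known non-small-cell
    histology using participant characteristics, study arm and detection
    mode; each of the ``m`` replicates draws a class per NOS case from the
    predicted probabilities.  SCLC is never assigned.  A cohort without NOS
    cases yields m identical copies.
    """
    from sklearn.linear_model import LogisticRegression

    df = cohort.records
    nos = (df["histology"] == "NOS").to_numpy()
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(max(m, 1)) % (2 ** 31)]
    if not nos.any():
        copies = [Cohort(df.copy(), cohort.trial, cohort.followup_cap)
                  for _ in range(m)]
        return ImputationSet(m, copies, 0, seeds[:m], [])

    known = df["histology"].isin(NSCLC_GROUPS).to_numpy()
    if not known.any():
        raise ValueError("no known-histology non-small-cell cases to train on")

    def features(sub: pd.DataFrame) -> np.ndarray:
        return np.column_stack([
            sub["age"].to_numpy(float),
            (sub["sex"] == "female").to_numpy(float),
            (sub["smoking_status"] == "current").to_numpy(float),
            sub["pack_years"].to_numpy(float),
            sub["years_quit"].to_numpy(float),
            (sub["arm"] == "CT").to_numpy(float),
            (sub["detection_mode"] == "screen").to_numpy(float),
        ])

    Xk = features(df[known])
    yk = df.loc[known, "histology"].to_numpy()
    classes = sorted(np.unique(yk))
    if len(classes) == 1:
        probs = np.ones((int(nos.sum()), 1))
    else:
        clf = LogisticRegression(max_iter=2000)
        clf.fit(Xk, yk)
        probs = clf.predict_proba(features(df[nos]))
        classes = list(clf.classes_)
    cum = np.cumsum(probs, axis=1)
    completed = []
    for rep in range(m):
        rng = np.random.default_rng(seeds[rep])
        u = rng.random(len(cum))
        pick = (u[:, None] > cum).sum(axis=1)
        out = df.copy()
        out.loc[nos, "histology"] = np.asarray(classes, dtype=object)[pick]
        completed.append(Cohort(out, cohort.trial, cohort.followup_cap))
    return ImputationSet(m, completed, 0, seeds[:m], ["histology"])
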
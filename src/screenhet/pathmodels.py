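"""Predictive modelling of screening-effect heterogeneity (PATH-style).

Two model families, both penalized logistic regressions on cumulative
lung-cancer mortality within the equalized follow-up window:

* **Risk-modelling** (two-stage): stage 1 estimates baseline LCM risk as a
  linear predictor *without* the screening assignment; stage 2 is an
  unpenalized logistic model of the outcome on the stage-1 linear predictor,
  screening assignment, and their interaction.  The stage-1 linear predictor
  can be substituted by an external risk-prediction score.  Screening
  effectiveness by risk interactions are tested by likelihood-ratio tests on
  the stage-2 scale.
* **Effect-modelling**: a single elastic-net logistic model with main
  effects, the screening indicator, and a limited prespecified set of
  screening-by-covariate interactions.  The screening main effect and the
  prespecified interactions are exempt from the penalty so that the estimand
  is not shrunk toward the null.

Both families support counterfactual prediction and are harmonized to
relative effectiveness by marginal standardization (g-computation): the
reported estimate is ``100 * (1 - sum p1 / sum p0)`` where ``p_a`` are
predicted risks with screening set to ``a`` for everyone, with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, outcome_events_and_time
from .penalized import (ElasticNetFit, LogisticFit, fit_elastic_net_logistic,
                        newton_logistic)
from .results import EffectEstimate

#: covariates entered into the models by default; continuous variables enter
#: linearly, categoricals are expanded to indicators
DEFAULT_COVARIATES = (
    "age", "sex", "smoking_status", "cigs_per_day", "years_smoked",
    "years_quit", "bmi", "copd", "personal_cancer_history",
)

DEFAULT_INTERACTION_SET = ("sex", "age", "pack_years", "smoking_status",
                           "years_quit")


def build_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design table from cohort columns.

    Numeric and boolean columns map to single terms; string/categorical
    columns expand to indicator terms ``col=level`` (first level by sort
    order is the reference).  The ``sex`` column maps to a single ``female``
    indicator (records of unknown sex score as the male reference so that
    overall analyses retain them); ``smoking_status`` maps to ``current``.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex":
            cols["female"] = (df["sex"] == "female").to_numpy(float)
            continue
        if cov == "smoking_status":
            cols["current"] = (df["smoking_status"] == "current").to_numpy(float)
            continue
        if cov == "trial":
            levels = sorted(df["trial"].astype(str).unique())
            for lev in levels[1:]:
                cols[f"trial={lev}"] = (df["trial"] == lev).to_numpy(float)
            continue
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in cohort")
        s = df[cov]
        if s.dtype == "boolean" or s.dtype == bool:
            cols[cov] = s.astype("boolean").fillna(False).to_numpy(float) \
                if s.isna().any() else s.to_numpy(float)
            if s.isna().any():
                raise ValueError(f"covariate {cov!r} has missing values; impute upstream")
            continue
        if s.dtype == object or str(s.dtype) == "category":
            levels = sorted(x for x in s.dropna().unique())
            for lev in levels[1:]:
                cols[f"{cov}={lev}"] = (s == lev).to_numpy(float)
            continue
        cols[cov] = s.to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"design has missing values in {bad}; impute upstream")
    return X


def _outcome_y(df: pd.DataFrame, outcome) -> np.ndarray:
    events, _ = outcome_events_and_time(df, outcome)
    return events.to_numpy(float)


def _outcome_label(outcome) -> str:
    return ":".join(map(str, outcome)) if isinstance(outcome, tuple) else str(outcome)


# ---------------------------------------------------------------------------
# two-stage risk model
# ---------------------------------------------------------------------------

@dataclass
class TwoStageRiskModel:
    """Stage-1 baseline-risk elastic net plus stage-2 treatment model.

    ``stage2`` regresses the outcome on {lp, screen, lp x screen} (or
    {lp, screen} when the interaction is disabled), unpenalized.  When an
    external risk score is substituted for stage 1, ``stage1`` is None and
    ``external_label`` names the score.
    """

    stage1: ElasticNetFit | None
    stage2: LogisticFit
    covariates: list[str]
    outcome: object
    trial: str
    interaction: bool = True
    external_label: str | None = None
    external_lp: np.ndarray | None = field(default=None, repr=False)

    @property
    def method_label(self) -> str:
        base = self.external_label or "internal"
        return f"risk_model[{base}]"

    def baseline_lp(self, df: pd.DataFrame) -> np.ndarray:
        if self.stage1 is not None:
            return self.stage1.linear_predictor(build_design(df, self.covariates))
        if self.external_lp is not None and len(self.external_lp) == len(df):
            return np.asarray(self.external_lp, dtype=float)
        raise ValueError("external-score model needs scores for this table; "
                         "pass them via with_external_lp()")

    def with_external_lp(self, lp: np.ndarray) -> "TwoStageRiskModel":
        return dc_replace(self, external_lp=np.asarray(lp, dtype=float))

    def _stage2_design(self, lp: np.ndarray, screen: np.ndarray) -> np.ndarray:
        cols = [lp, screen]
        if self.interaction:
            cols.append(lp * screen)
        return np.column_stack(cols)

    def predict_counterfactual(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        lp = self.baseline_lp(df)
        zeros = np.zeros(len(df))
        ones = np.ones(len(df))
        p0 = self.stage2.predict(self._stage2_design(lp, zeros))
        p1 = self.stage2.predict(self._stage2_design(lp, ones))
        return p0, p1

    def refit(self, cohort: Cohort, seed: int = 0, refit_cv: bool = False) -> "TwoStageRiskModel":
        """Refit on (resampled) data: stage 1 at the stored (alpha, lambda)
        unless ``refit_cv``, stage 2 always."""
        lambda_ = None if refit_cv else (self.stage1.lambda_ if self.stage1 else None)
        folds = self.stage1.cv_folds if (self.stage1 and refit_cv) else 10
        return fit_two_stage_risk_model(
            cohort, self.covariates, outcome=self.outcome,
            alpha_mix=self.stage1.alpha_mix if self.stage1 else 0.5,
            folds=folds, seed=seed, interaction=self.interaction,
            external_lp=None if self.stage1 is not None else self.external_lp,
            external_label=self.external_label, lambda_=lambda_)

    def to_dict(self) -> dict:
        return {
            "kind": "two_stage_risk_model",
            "stage1": self.stage1.to_dict() if self.stage1 else None,
            "stage2": {"terms": self.stage2.terms,
                       "coef": list(self.stage2.coef)},
            "covariates": self.covariates,
            "outcome": _outcome_label(self.outcome),
            "trial": self.trial,
            "interaction": self.interaction,
            "external_label": self.external_label,
        }


def fit_two_stage_risk_model(
    cohort: Cohort,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome="overall_lcm",
    alpha_mix: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    interaction: bool = True,
    external_lp: np.ndarray | None = None,
    external_label: str | None = None,
    lambda_: float | None = None,
    nlambda: int = 30,
) -> TwoStageRiskModel:
    """Fit the two-stage risk model on a complete-case or imputed cohort.

    Stage 1 never sees the arm; stage 2 is an unpenalized logistic model on
    {lp, screen, lp x screen}.  Supplying ``external_lp`` (a per-record
    baseline-risk linear predictor from a published risk-prediction model)
    skips stage 1.
    """
    df = cohort.records
    y = _outcome_y(df, outcome)
    if external_lp is not None:
        stage1 = None
        lp = np.asarray(external_lp, dtype=float)
        if len(lp) != len(df):
            raise ValueError("external_lp length does not match cohort")
    else:
        X = build_design(df, covariates)
        if "screen" in X.columns or "arm" in covariates:
            raise ValueError("stage 1 must not include the screening assignment")
        stage1 = fit_elastic_net_logistic(X, y, alpha_mix=alpha_mix,
                                          folds=folds, seed=seed,
                                          lambda_=lambda_, nlambda=nlambda)
        lp = stage1.linear_predictor(X)
    screen = (df["arm"] == "CT").to_numpy(float)
    cols = [lp, screen] + ([lp * screen] if interaction else [])
    names = ["lp", "screen"] + (["lp_x_screen"] if interaction else [])
    stage2 = newton_logistic(np.column_stack(cols), y, terms=names)
    return TwoStageRiskModel(stage1, stage2, list(covariates), outcome,
                             cohort.trial, interaction, external_label,
                             external_lp=None if external_lp is None else lp)


def lr_interaction_test(model_full: LogisticFit | TwoStageRiskModel,
                        model_reduced: LogisticFit | TwoStageRiskModel,
                        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested unpenalized (stage-2 scale) models.

    Returns ``(statistic, df, p_value)`` with the statistic floored at zero
    and the p-value from the chi-square reference distribution.
    """
    full = model_full.stage2 if isinstance(model_full, TwoStageRiskModel) else model_full
    red = model_reduced.stage2 if isinstance(model_reduced, TwoStageRiskModel) else model_reduced
    if not set(red.terms) <= set(full.terms):
        raise ValueError(f"models are not nested: {red.terms} vs {full.terms}")
    if red.n != full.n:
        raise ValueError("models fit on different data")
    df = full.df - red.df
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = 2.0 * (full.loglik - red.loglik)
    if stat < -1e-6:
        raise ValueError("reduced model has higher likelihood; models not nested")
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------

@dataclass
class EffectModelFit:
    """Elastic-net logistic model with explicit screening interactions.

    ``base`` is fit on main effects + ``screen`` + ``screen:<term>``
    interactions for the prespecified ``interaction_set``; the screening
    terms carry penalty factor 0.
    """

    base: ElasticNetFit
    covariates: list[str]
    interaction_set: list[str]
    outcome: object
    trial: str

    method_label: str = "effect_model"

    def _design(self, df: pd.DataFrame, screen: np.ndarray) -> pd.DataFrame:
        X = build_design(df, self.covariates)
        X["screen"] = screen
        for term in _interaction_terms(X, self.interaction_set):
            X[f"screen:{term}"] = X[term] * screen
        return X

    def predict_counterfactual(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        p0 = self.base.predict_proba(self._design(df, np.zeros(len(df))))
        p1 = self.base.predict_proba(self._design(df, np.ones(len(df))))
        return p0, p1

    def refit(self, cohort: Cohort, seed: int = 0, refit_cv: bool = False) -> "EffectModelFit":
        return fit_effect_model(
            cohort, self.covariates, self.interaction_set, outcome=self.outcome,
            alpha_mix=self.base.alpha_mix, seed=seed,
            lambda_=None if refit_cv else self.base.lambda_)

    def to_dict(self) -> dict:
        return {"kind": "effect_model", "base": self.base.to_dict(),
                "covariates": self.covariates,
                "interaction_set": self.interaction_set,
                "outcome": _outcome_label(self.outcome), "trial": self.trial}


def _interaction_terms(X: pd.DataFrame, interaction_set: Sequence[str]) -> list[str]:
    """Design terms generated by the interaction covariates."""
    out = []
    mapping = {"sex": ["female"], "smoking_status": ["current"]}
    for cov in interaction_set:
        if cov in mapping:
            out.extend(t for t in mapping[cov] if t in X.columns)
        elif cov in X.columns:
            out.append(cov)
        else:
            pref = [c for c in X.columns if c.startswith(f"{cov}=")]
            if not pref:
                raise ValueError(f"interaction covariate {cov!r} not in design")
            out.extend(pref)
    return out


def fit_effect_model(
    cohort: Cohort,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    interaction_set: Sequence[str] = DEFAULT_INTERACTION_SET,
    outcome="overall_lcm",
    alpha_mix: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    nlambda: int = 30,
) -> EffectModelFit:
    """Fit the effect model (prespecified screening interactions only).

    Covariates named in ``interaction_set`` but absent from ``covariates``
    are added as main effects so the interaction hierarchy is respected.
    """
    covs = list(covariates)
    for cov in interaction_set:
        if cov not in covs and cov not in ("sex", "smoking_status"):
            if cov not in cohort.records.columns:
                raise ValueError(f"interaction covariate {cov!r} missing from cohort")
        if cov not in covs:
            covs.append(cov)
    df = cohort.records
    y = _outcome_y(df, outcome)
    screen = (df["arm"] == "CT").to_numpy(float)
    X = build_design(df, covs)
    inter_terms = _interaction_terms(X, interaction_set)
    X["screen"] = screen
    pf = {"screen": 0.0}
    for term in inter_terms:
        X[f"screen:{term}"] = X[term] * screen
        pf[f"screen:{term}"] = 0.0
    fit = fit_elastic_net_logistic(X, y, alpha_mix=alpha_mix, folds=folds,
                                   seed=seed, penalty_factor=pf,
                                   lambda_=lambda_, nlambda=nlambda)
    return EffectModelFit(fit, covs, list(interaction_set), outcome, cohort.trial)


# ---------------------------------------------------------------------------
# standardization (g-computation) and pooling
# ---------------------------------------------------------------------------

def _standardized_point(model, df: pd.DataFrame,
                        mask: np.ndarray | None) -> tuple[float, float, str | None]:
    p0, p1 = model.predict_counterfactual(df)
    if mask is not None:
        p0, p1 = p0[mask], p1[mask]
    s0 = p0.sum()
    if s0 <= 0:
        return np.nan, np.nan, "standardized control risk is zero"
    rel = 100.0 * (1.0 - p1.sum() / s0)
    absb = 1000.0 * float(np.mean(p0 - p1))
    return rel, absb, None


def standardized_effectiveness(
    model,
    cohort: Cohort,
    subgroup=None,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    refit_cv: bool = False,
    outcome=None,
) -> EffectEstimate:
    """Marginal standardization of a counterfactual model to an effect cell.

    ``subgroup`` is a predicate on the record table (or a boolean mask);
    the model itself is fit on the full cohort -- only the standardization
    population is restricted.  The percentile bootstrap resamples records
    within arms and refits the model's prediction layers (stage 2 always;
    stage 1 / the penalized base at fixed lambda, or with full CV re-selection
    when ``refit_cv``).
    """
    df = cohort.records
    mask = _subgroup_mask(df, subgroup)
    outcome = outcome if outcome is not None else getattr(model, "outcome", "overall_lcm")
    rel, absb, flag = _standardized_point(model, df, mask)
    events = int(_outcome_y(df if mask is None else df[mask], outcome).sum())
    n = len(df) if mask is None else int(mask.sum())

    rel_ci = (np.nan, np.nan)
    abs_ci = (np.nan, np.nan)
    if B and B > 0 and flag is None:
        rng = np.random.default_rng(seed)
        ct_idx = np.flatnonzero((df["arm"] == "CT").to_numpy())
        c_idx = np.flatnonzero((df["arm"] == "control").to_numpy())
        boot = _make_bootstrap_evaluator(model, cohort, subgroup, refit_cv,
                                         outcome)
        rels = np.empty(B)
        abss = np.empty(B)
        for b in range(B):
            take = np.r_[rng.choice(ct_idx, len(ct_idx)),
                         rng.choice(c_idx, len(c_idx))]
            try:
                rels[b], abss[b] = boot(take, seed + b + 1)
            except (RuntimeError, np.linalg.LinAlgError):
                rels[b], abss[b] = np.nan, np.nan
        qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
        ok = np.isfinite(rels)
        if ok.sum() >= max(10, B // 2):
            rel_ci = tuple(np.nanpercentile(rels[ok], qs))
            abs_ci = tuple(np.nanpercentile(abss[ok], qs))
            rel_ci = (min(rel_ci[0], rel), max(rel_ci[1], rel))
            abs_ci = (min(abs_ci[0], absb), max(abs_ci[1], absb))
        else:
            flag = "bootstrap failed in most resamples"

    return EffectEstimate(
        method=getattr(model, "method_label", type(model).__name__),
        trial=cohort.trial, outcome=_outcome_label(outcome),
        subgroup=_subgroup_label(subgroup), relative_pct=rel,
        abs_per_1000=absb, rel_ci=rel_ci, abs_ci=abs_ci,
        n_events=events, n=n, flagged=flag)


def _make_bootstrap_evaluator(model, cohort: Cohort, subgroup, refit_cv: bool,
                              outcome):
    """Closure computing one bootstrap replicate of the standardized
    estimates from resampled row indices, at the array level.

    The penalized layer is refit at the lambda selected on the full data
    (or with full CV re-selection when ``refit_cv``); the unpenalized
    stage-2 layer is always refit.  External risk scores are frozen and
    simply resampled.
    """
    from .penalized import fit_enet_raw

    df = cohort.records
    y = _outcome_y(df, outcome)
    screen = (df["arm"] == "CT").to_numpy(float)
    mask_full = _subgroup_mask(df, subgroup)
    if mask_full is None:
        mask_full = np.ones(len(df), dtype=bool)

    if isinstance(model, TwoStageRiskModel):
        X1 = (build_design(df, model.covariates).to_numpy(float)
              if model.stage1 is not None else None)
        lp_ext = model.external_lp if model.stage1 is None else None
        s1 = model.stage1

        def run(take: np.ndarray, seed: int) -> tuple[float, float]:
            yb, sb, mb = y[take], screen[take], mask_full[take]
            if X1 is not None:
                Xb = X1[take]
                if refit_cv:
                    fit = fit_elastic_net_logistic(
                        pd.DataFrame(Xb, columns=s1.terms), yb,
                        alpha_mix=s1.alpha_mix, folds=s1.cv_folds or 10,
                        seed=seed)
                    lp = fit.linear_predictor(pd.DataFrame(Xb, columns=s1.terms))
                else:
                    pf = np.array([s1.penalty_factor[t] for t in s1.terms])
                    init = (s1.intercept,
                            np.array([s1.coefficients[t] for t in s1.terms]))
                    b0, beta = fit_enet_raw(Xb, yb, s1.alpha_mix, s1.lambda_,
                                            pf, tol=3e-5, init=init)
                    lp = b0 + Xb @ beta
            else:
                lp = lp_ext[take]
            cols = [lp, sb] + ([lp * sb] if model.interaction else [])
            s2 = newton_logistic(np.column_stack(cols), yb)
            z = np.zeros(len(take))
            o = np.ones(len(take))
            mk = lambda s: np.column_stack([lp, s] + ([lp * s] if model.interaction else []))
            p0 = s2.predict(mk(z))[mb]
            p1 = s2.predict(mk(o))[mb]
            return (100.0 * (1.0 - p1.sum() / p0.sum()),
                    1000.0 * float(np.mean(p0 - p1)))

        return run

    if isinstance(model, EffectModelFit):
        base = model.base
        Xfit = model._design(df, screen)[base.terms].to_numpy(float)
        X0 = model._design(df, np.zeros(len(df)))[base.terms].to_numpy(float)
        X1 = model._design(df, np.ones(len(df)))[base.terms].to_numpy(float)
        pf = np.array([base.penalty_factor[t] for t in base.terms])

        def run(take: np.ndarray, seed: int) -> tuple[float, float]:
            yb, mb = y[take], mask_full[take]
            if refit_cv:
                fit = fit_elastic_net_logistic(
                    pd.DataFrame(Xfit[take], columns=base.terms), yb,
                    alpha_mix=base.alpha_mix, folds=base.cv_folds or 10,
                    seed=seed, penalty_factor=dict(base.penalty_factor))
                b0 = fit.intercept
                beta = np.array([fit.coefficients[t] for t in base.terms])
            else:
                init = (base.intercept,
                        np.array([base.coefficients[t] for t in base.terms]))
                b0, beta = fit_enet_raw(Xfit[take], yb, base.alpha_mix,
                                        base.lambda_, pf, tol=3e-5, init=init)
            p0 = 1.0 / (1.0 + np.exp(-np.clip(b0 + X0[take] @ beta, -30, 30)))[mb]
            p1 = 1.0 / (1.0 + np.exp(-np.clip(b0 + X1[take] @ beta, -30, 30)))[mb]
            return (100.0 * (1.0 - p1.sum() / p0.sum()),
                    1000.0 * float(np.mean(p0 - p1)))

        return run

    # generic (slow) path for other counterfactual models with .refit
    def run(take: np.ndarray, seed: int) -> tuple[float, float]:
        bdf = df.iloc[take].reset_index(drop=True)
        bco = Cohort(bdf, cohort.trial, cohort.followup_cap)
        bmodel = model.refit(bco, seed=seed, refit_cv=refit_cv)
        bmask = _subgroup_mask(bdf, subgroup)
        rel, absb, _ = _standardized_point(bmodel, bdf, bmask)
        return rel, absb

    return run


def _subgroup_mask(df: pd.DataFrame, subgroup) -> np.ndarray | None:
    if subgroup is None:
        return None
    if callable(subgroup):
        return np.asarray(subgroup(df)).astype(bool)
    if isinstance(subgroup, tuple) and len(subgroup) == 2:
        return (df[subgroup[0]] == subgroup[1]).to_numpy()
    return np.asarray(subgroup).astype(bool)


def _subgroup_label(subgroup) -> str:
    if subgroup is None:
        return "overall"
    if isinstance(subgroup, tuple) and len(subgroup) == 2:
        return f"{subgroup[0]}={subgroup[1]}"
    return getattr(subgroup, "__name__", "subgroup")


def fit_pooled(
    cohorts: Sequence[Cohort],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    kind: str = "risk",
    **options,
):
    """Pooled individual-level fit across trials with a trial indicator.

    The concatenated cohort carries a ``trial`` covariate; per-trial
    effectiveness is then estimable by standardizing within trial
    (``subgroup=("trial", label)``).  Schemas must agree.
    """
    if len(cohorts) < 1:
        raise ValueError("need at least one cohort")
    cols = set(cohorts[0].records.columns)
    for c in cohorts[1:]:
        if set(c.records.columns) != cols:
            raise ValueError(
                f"schema mismatch: {sorted(cols ^ set(c.records.columns))}")
    df = pd.concat([c.records for c in cohorts], ignore_index=True)
    df["id"] = df["trial"].astype(str) + ":" + df["id"].astype(str)
    pooled = Cohort(df, trial="POOLED",
                    followup_cap=min(c.followup_cap for c in cohorts))
    covs = list(covariates)
    if len({c.trial for c in cohorts}) > 1 and "trial" not in covs:
        covs.append("trial")
    if kind == "risk":
        return fit_two_stage_risk_model(pooled, covs, **options)
    if kind == "effect":
        return fit_effect_model(pooled, covs, **options)
    raise ValueError(f"unknown pooled model kind {kind!r}")
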
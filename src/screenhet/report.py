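"""Cross-method aggregation and the end-to-end pipeline driver.

The reporting surface is tidy long-format tables (one row per method x
outcome x subgroup x trial).  Aggregation across methods follows the
median-of-medians presentation: the aggregated point estimate is the median
of the member point estimates, and the aggregated interval bounds are the
medians of the member lower and upper bounds.  The aggregated interval is a
presentation device, not a frequentist confidence interval, and is reported
as such.

``run_pipeline`` executes simulate/load -> eligibility filters -> follow-up
truncation -> missingness/imputation -> method fits -> effectiveness
estimates for every (outcome x subgroup) cell -> external validation (when
two cohorts are configured) -> aggregation, writing tidy CSVs and a run log.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (Cohort, HISTOLOGY_GROUPS, apply_eligibility_filters,
                     categorize_covariates, load_cohort, truncate_follow_up,
                     write_cohort, write_exclusion_log)
from .results import EffectEstimate

log = logging.getLogger("screenhet")


@dataclass
class MethodPanel:
    """Estimates for one (outcome, subgroup) cell across methods."""

    outcome: str
    subgroup: str
    trial: str
    estimates: list[EffectEstimate]
    point: float
    ci_low: float
    ci_high: float


def aggregate_across_methods(estimates: Sequence[EffectEstimate]) -> MethodPanel:
    """Median of points and of CI bounds across methods for one cell.

    All member estimates must share (outcome, subgroup); an even method
    count takes the mean of the central pair (numpy median).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    keys = {(e.outcome, e.subgroup) for e in estimates}
    if len(keys) > 1:
        raise ValueError(f"mixed cells in one panel: {sorted(keys)}")
    pts = np.array([e.relative_pct for e in estimates], dtype=float)
    los = np.array([e.rel_ci[0] for e in estimates], dtype=float)
    his = np.array([e.rel_ci[1] for e in estimates], dtype=float)
    ok = np.isfinite(pts)
    outcome, subgroup = next(iter(keys))
    return MethodPanel(
        outcome=outcome, subgroup=subgroup,
        trial=estimates[0].trial, estimates=list(estimates),
        point=float(np.median(pts[ok])) if ok.any() else float("nan"),
        ci_low=float(np.nanmedian(los)) if np.isfinite(los).any() else float("nan"),
        ci_high=float(np.nanmedian(his)) if np.isfinite(his).any() else float("nan"))


DEFAULT_CONFIG: dict = {
    "seed": 12345,
    "trials": [{"style": "nelson", "n_per_arm": 4000},
               {"style": "nlst", "n_per_arm": 4000}],
    "methods": ["rate_ratio", "risk_model", "effect_model", "causal_forest"],
    "risk_scores": ["internal"],
    "outcomes": ["overall"] + list(HISTOLOGY_GROUPS),
    "subgroup_vars": ["sex", "smoking_status", "pack_years_group"],
    "categorize": {"pack_years": [30, 40, 50], "years_quit": [5, 10],
                   "age": [55, 60, 65, 70]},
    "eligibility_rules": ["never_smoker", "prior_lc", "missing_incidence_date"],
    "imputation": {"m": 1, "k": 5},
    "bootstrap_B": 100,
    "bootstrap_B_subgroups": 0,
    "forest": {"num_trees": 200, "max_depth": 6},
    "quintile_models": ["PLCOm2012"],
    "external_validation": True,
    "benjamini_hochberg": False,
}


def _merged_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        cfg[k] = v
    return cfg


def _prepare_trial(spec: dict, cfg: dict, seed: int, out: Path):
    """simulate or load -> filter -> truncate -> missingness -> impute ->
    categorize; returns (analysis cohort, ground truth or None, logs)."""
    from .impute import knn_impute, multiply_impute
    from .simulate import (inject_missingness, nelson_like_config,
                           nlst_like_config, simulate_cohort)

    truth = None
    if "path" in spec:
        cohort = load_cohort(spec["path"])
        if cohort.rejected:
            log.warning("%d rows rejected while loading %s", len(cohort.rejected),
                        spec["path"])
    else:
        maker = {"nelson": nelson_like_config, "nlst": nlst_like_config}[
            spec.get("style", "nelson")]
        sim_cfg = maker(n_per_arm=int(spec.get("n_per_arm", 4000)), seed=seed)
        cohort, truth = simulate_cohort(sim_cfg)
        cohort = inject_missingness(cohort, sim_cfg)
    cohort, excl = apply_eligibility_filters(cohort, cfg["eligibility_rules"])
    cap = spec.get("followup_cap") or cohort.followup_cap
    cohort = truncate_follow_up(cohort, float(cap))
    m = int(cfg["imputation"].get("m", 1))
    k = int(cfg["imputation"].get("k", 5))
    if m <= 1:
        cohort = knn_impute(cohort, k=k, seed=seed + 7)
    else:
        # analyses below run on the first completed replicate; the full set is
        # written out for replicate-level analyses
        imp = multiply_impute(cohort, m=m, k=k, master_seed=seed + 7)
        cohort = imp.completed_cohorts[0]
    cohort = categorize_covariates(cohort, cfg["categorize"])
    write_exclusion_log(excl, out / f"exclusions_{cohort.trial}.csv")
    return cohort, truth, excl


def _rate_ratio_estimates(cohort, cfg) -> list[EffectEstimate]:
    from .rates import overall_table, subgroup_table

    out = []

    def from_row(row, outcome, subgroup) -> EffectEstimate:
        return EffectEstimate(
            method="rate_ratio", trial=cohort.trial, outcome=outcome,
            subgroup=subgroup, relative_pct=row["estimate_pct"],
            abs_per_1000=np.nan, rel_ci=(row["ci_low"], row["ci_high"]),
            n_events=int(row["events_ct"] + row["events_ctrl"]),
            n=cohort.n, flagged=row["flagged"])

    for outc in cfg["outcomes"]:
        spec = "overall_lcm" if outc == "overall" else ("lcm", outc)
        row = overall_table(cohort, outcome=spec).iloc[0]
        out.append(from_row(row, outc, "overall"))
    for var in cfg["subgroup_vars"]:
        tab = subgroup_table(cohort, var, outcome="overall_lcm")
        for _, row in tab.iterrows():
            if row["comparison"] is None:
                continue
            out.append(from_row(row, "overall",
                                f"{var}={row['subgroup_level']}"))
    return out


def _stable_seed(*parts) -> int:
    return zlib.crc32(repr(parts).encode()) % 2 ** 31


def _model_estimates(model_factory, label, cohort, cfg):
    """Fit one model family per outcome; standardize overall + subgroups.

    Returns the estimate list and the fitted overall-outcome model (kept for
    benefit metrics and external validation)."""
    from .pathmodels import standardized_effectiveness

    B = int(cfg["bootstrap_B"])
    Bs = int(cfg["bootstrap_B_subgroups"])
    out = []
    overall_model = None
    for outc in cfg["outcomes"]:
        spec = "overall_lcm" if outc == "overall" else ("lcm", outc)
        model = model_factory(spec)
        if outc == "overall":
            overall_model = model
        est = standardized_effectiveness(model, cohort, B=B,
                                         seed=_stable_seed(label, outc))
        out.append(_relabel(est, outc, "overall"))
        if outc == "overall":
            for var in cfg["subgroup_vars"]:
                levels = sorted(cohort.records[var].dropna().unique())
                for lev in levels:
                    e = standardized_effectiveness(
                        model, cohort, subgroup=(var, lev), B=Bs,
                        seed=_stable_seed(label, var, lev))
                    out.append(_relabel(e, outc, f"{var}={lev}"))
    return out, overall_model


def _forest_estimates(cohort, cfg, seed) -> tuple[list[EffectEstimate], object]:
    from .forest import ForestParams, fit_causal_forest, forest_effectiveness

    params = ForestParams(seed=seed, **cfg["forest"])
    out = []
    overall_model = None
    for outc in cfg["outcomes"]:
        spec = "overall_lcm" if outc == "overall" else ("lcm", outc)
        model = fit_causal_forest(cohort, params=params, outcome=spec)
        if outc == "overall":
            overall_model = model
        out.append(_relabel(forest_effectiveness(model, cohort), outc, "overall"))
        if outc == "overall":
            for var in cfg["subgroup_vars"]:
                for lev in sorted(cohort.records[var].dropna().unique()):
                    out.append(_relabel(
                        forest_effectiveness(model, cohort, subgroup=(var, lev)),
                        outc, f"{var}={lev}"))
    return out, overall_model


def _relabel(est: EffectEstimate, outcome: str, subgroup: str) -> EffectEstimate:
    from dataclasses import replace
    return replace(est, outcome=outcome, subgroup=subgroup)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Execute the full comparative analysis; returns the result bundle.

    The bundle maps trial labels to estimate tables plus the aggregated
    panels, quintile tables and benefit metrics; everything is also written
    under ``out_dir`` as CSV.  Fully reproducible from the config and seed.
    """
    from .metrics import evaluate_model, external_validate
    from .pathmodels import (fit_effect_model, fit_two_stage_risk_model,
                             standardized_effectiveness)
    from .riskmodels import effectiveness_by_risk_quintile, score_cohort

    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    t0 = time.time()
    bundle: dict = {"config": cfg, "trials": {}}

    cohorts: dict[str, Cohort] = {}
    truths = {}
    stage = "prepare"
    try:
        for i, spec in enumerate(cfg["trials"]):
            cohort, truth, _ = _prepare_trial(spec, cfg, seed + 100 * i, out)
            cohorts[cohort.trial] = cohort
            truths[cohort.trial] = truth
            write_cohort(cohort, out / f"cohort_{cohort.trial}.csv")
            log.info("prepared %s: n=%d arms=%s", cohort.trial, cohort.n,
                     cohort.arm_counts)

        dev_models: dict[str, dict] = {}
        for label, cohort in cohorts.items():
            stage = f"estimate[{label}]"
            estimates: list[EffectEstimate] = []
            models: dict[str, object] = {}
            if "rate_ratio" in cfg["methods"]:
                estimates += _rate_ratio_estimates(cohort, cfg)
            if "risk_model" in cfg["methods"]:
                factory = lambda spec_, c=cohort: fit_two_stage_risk_model(
                    c, seed=seed, outcome=spec_)
                ests, mdl = _model_estimates(factory, "risk_model", cohort, cfg)
                estimates += ests
                models["risk_model"] = mdl
            if "effect_model" in cfg["methods"]:
                factory = lambda spec_, c=cohort: fit_effect_model(
                    c, seed=seed, outcome=spec_)
                ests, mdl = _model_estimates(factory, "effect_model", cohort, cfg)
                estimates += ests
                models["effect_model"] = mdl
            if "causal_forest" in cfg["methods"]:
                ests, fmodel = _forest_estimates(cohort, cfg, seed)
                estimates += ests
                models["causal_forest"] = fmodel
            dev_models[label] = models

            stage = f"quintiles[{label}]"
            quintiles = {}
            for qm in cfg["quintile_models"]:
                scores = score_cohort(cohort, qm)["probability"].to_numpy()
                quintiles[qm] = effectiveness_by_risk_quintile(cohort, scores)

            stage = f"aggregate[{label}]"
            est_df = pd.DataFrame([e.to_row() for e in estimates])
            cells = est_df.groupby(["outcome", "subgroup"]).groups
            panels = []
            for (outc, sg), idx in cells.items():
                members = [estimates[i] for i in idx]
                panel = aggregate_across_methods(members)
                panels.append({"trial": label, "outcome": outc, "subgroup": sg,
                               "n_methods": len(members), "point": panel.point,
                               "ci_low": panel.ci_low, "ci_high": panel.ci_high})
            panel_df = pd.DataFrame(panels)
            if cfg.get("benjamini_hochberg"):
                from .rates import benjamini_hochberg
                rr = est_df["method"] == "rate_ratio"
                if "p_value" in est_df.columns and rr.any():
                    est_df.loc[rr, "p_adj_bh"] = benjamini_hochberg(
                        est_df.loc[rr, "p_value"])
            est_df.to_csv(out / f"estimates_{label}.csv", index=False)
            panel_df.to_csv(out / f"panels_{label}.csv", index=False)
            for qm, qtab in quintiles.items():
                qtab.to_csv(out / f"quintiles_{label}_{qm}.csv", index=False)
            bundle["trials"][label] = {"estimates": est_df, "panels": panel_df,
                                       "quintiles": quintiles,
                                       "truth": truths[label]}

        stage = "validation"
        if cfg.get("external_validation") and len(cohorts) == 2:
            rows = []
            labels = list(cohorts)
            for dev in labels:
                val = [l for l in labels if l != dev][0]
                for mname, model in dev_models[dev].items():
                    if model is None:
                        continue
                    try:
                        rep = external_validate(model, dev, cohorts[val])
                    except ValueError as exc:
                        log.warning("validation of %s %s failed: %s", dev,
                                    mname, exc)
                        continue
                    dev_eval = evaluate_model(model, cohorts[dev])
                    rows.append({
                        "method": mname, "development": dev, "validation": val,
                        "c_statistic_dev": dev_eval.c_statistic,
                        "c_statistic_val": rep.evaluation_absolute.c_statistic,
                        "c_for_benefit_dev": dev_eval.c_for_benefit,
                        "c_for_benefit_val": rep.evaluation_absolute.c_for_benefit,
                        "cal_slope_dev": dev_eval.calibration_slope,
                        "cal_slope_val": rep.evaluation_absolute.calibration_slope,
                        "cal_intercept_val": rep.evaluation_absolute.calibration_intercept,
                        "rel_pct_val": rep.estimates[0].relative_pct,
                    })
            vdf = pd.DataFrame(rows)
            vdf.to_csv(out / "external_validation.csv", index=False)
            bundle["external_validation"] = vdf
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run.json", "w") as fh:
        json.dump({"config": _jsonable(cfg), "elapsed_s": time.time() - t0},
                  fh, indent=1)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return float(obj)
    return obj
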
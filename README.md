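# screenhet

Heterogeneity of lung-cancer screening effectiveness in two-arm randomized
trials, analysed comparatively: traditional subgroup analyses, PATH-style
predictive modelling, and machine learning, all harmonized to one estimand.

Low-dose CT screening reduces lung-cancer mortality (LCM), but by how much
depends on who is screened — and, it turns out, mostly on *which histology*
they would develop. This package is for biostatisticians and screening
researchers who want to quantify that heterogeneity in person-level trial
data (or realistic synthetic stand-ins), compare methods on common inputs,
and evaluate how well models predict individual screening benefit.

## What it computes

For a two-arm cohort (CT vs control) with harmonized baseline risk factors
and an equalized follow-up window, *screening effectiveness* is the relative
LCM reduction `100 × (1 − RR)`. Four method families estimate it overall,
by histology-specific mortality (ADN, SQM, OTH, SCLC), and by subgroup:

* **Exact rate ratios** — one variable at a time, conditioning on the total
  event count: `x_CT | T ~ Binomial(T, RR·PY₁/(RR·PY₁+PY₀))`, with
  Clopper–Pearson intervals mapped to the rate-ratio scale, plus rate
  differences per 1000 person-years.
* **Risk-modelling (two-stage)** — an elastic-net logistic model of baseline
  risk without the screening assignment, then an unpenalized logistic model
  on {linear predictor, screening, interaction}; interactions tested by
  likelihood ratio. Published risk scores (PLCOm2012) can replace stage 1,
  and effectiveness is also reported by baseline-risk quintile.
* **Effect-modelling** — one elastic-net logistic model with prespecified
  screening-by-covariate interactions, unpenalized where the estimand lives.
* **Honest causal forest** — per-individual absolute effects (CATE) from
  honest trees (split data and estimation data disjoint), 2000 trees by
  default, with little-bag variance estimates.

Model families are harmonized by g-computation (standardized counterfactual
risks) and aggregated across methods by medians of points and interval
bounds. Model evaluation follows the benefit-prediction playbook:
C-statistic, C-for-benefit over rank-matched pairs, calibration-for-benefit,
and frozen-model external validation between cohorts. Missing covariates
are handled by k-nearest-neighbour multiple imputation (k = 5, m = 30)
pooled with Rubin's rules; a sensitivity analysis reassigns NOS histology
codes by multinomial imputation.

Because the trial datasets this design targets are access-restricted, the
package ships a first-class synthetic generator: blocked stratified
randomization, covariate-dependent histology mixtures, and
histology-specific screening effects realized as a late-to-early stage
shift. Its key property is *emergent* heterogeneity — screening effects
that differ only by histology produce higher overall effectiveness in
women, former smokers and lighter smokers purely through the case mix, the
mechanism the comparative analysis is built to detect. See
`docs/methods.md` for the full model description.

## Worked example

```python
from screenhet import (nelson_like_config, simulate_cohort,
                       fit_two_stage_risk_model, standardized_effectiveness,
                       exact_rate_ratio, person_years)

cohort, truth = simulate_cohort(nelson_like_config(n_per_arm=20000, seed=3))
print(f"true effectiveness {100*truth.true_overall_relative_effectiveness:.1f}%")

py = person_years(cohort).set_index("arm")
rr = exact_rate_ratio(int(py.loc['CT','events']), py.loc['CT','person_years'],
                      int(py.loc['control','events']), py.loc['control','person_years'])
print(f"rate ratio    {100*(1-rr.rate_ratio):.1f}% "
      f"(95% CI {rr.effectiveness_ci_pct[0]:.1f} to {rr.effectiveness_ci_pct[1]:.1f})")

model = fit_two_stage_risk_model(cohort, seed=1)
est = standardized_effectiveness(model, cohort, B=200, seed=2)
print(f"risk model    {est.relative_pct:.1f}% "
      f"(95% CI {est.rel_ci[0]:.1f} to {est.rel_ci[1]:.1f})")
```

prints

```
true effectiveness 26.8%
rate ratio    29.7% (95% CI 20.2 to 38.1)
risk model    29.7% (95% CI 20.9 to 37.0)
```

The generator's analytic estimand for this replicate is a 26.8% mortality
reduction; both the exact rate ratio and the standardized two-stage model
estimate 29.7% (sampling noise of this one replicate — the parameter-recovery
test in `tests/test_acceptance.py` shows the bias across replicates is under
3 points) with intervals comfortably covering the truth.

The full pipeline — simulate or load two trials, filter, truncate, impute,
fit every method, estimate all outcome-by-subgroup cells, validate across
trials, aggregate — runs from the command line:

```
screenhet run-all --seed 12345 --out-dir results/
```

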
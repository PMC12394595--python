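# Methods

`screenhet` implements a comparative analysis of heterogeneity in lung-cancer
screening effectiveness for two-arm randomized trials of low-dose CT
screening. This note records the statistical models, the synthetic-trial
generator that stands in for restricted trial data, the numerical choices,
and the limits of what the package's tests demonstrate.

## Estimand and outcome scale

The outcome throughout is cumulative lung-cancer mortality (LCM) within an
equalized follow-up window since randomization (10 years for the NELSON-like
configuration, 7 for the NLST-like one). *Screening effectiveness* is the
relative reduction in LCM in the CT arm versus control,
`100 × (1 − risk ratio)`, with absolute benefit reported as deaths prevented
per 1000 randomized participants. Mortality is analysed rather than
survival because survival of screen-detected cases is distorted by lead-time
and length-time bias. All model-based analyses use a binary outcome within
the window rather than time-to-event; person-time differences are handled
upstream by follow-up truncation, and the rate analyses account for
person-time explicitly (deaths contribute person-time to the death time,
everyone else to the end of follow-up — for incidence outcomes, cases
contribute to diagnosis).

## One-variable-at-a-time analyses

Exact rate-ratio inference conditions on the total event count: with
`x1 ~ Poisson(r1·PY1)` and `x0 ~ Poisson(r0·PY0)`, given `T = x1 + x0` the
CT count is `Binomial(T, RR·PY1/(RR·PY1 + PY0))`. Two-sided p-values use
the doubling convention `min(1, 2·min(tails))`; confidence limits are
Clopper–Pearson beta quantiles mapped back to the rate-ratio scale. These
intervals are conservative by construction. Rate differences per 1000
person-years use independent Poisson variances on the rate scale with a
normal interval and no continuity correction; zero cells contribute zero
variance and are flagged. Histology-specific mortality treats deaths from
other histologies as non-events (not competing-risk censoring), matching
the cited subgroup-analysis tradition; the same convention is used for
histology- and stage-specific incidence. Continuous variables are
categorized with left-closed/right-open intervals (last interval closed),
labels mirroring the printed groups (`<30`, `30–39`, `40–49`, `>50`).

## Penalized models (PATH-style)

Both predictive families are elastic-net logistic regressions solved by an
in-package IRLS + coordinate-descent solver (covariance-update form, so a
coordinate sweep is O(p²) independent of n) over a 30-point log-spaced
lambda path with warm starts; 10-fold event-stratified cross-validated
binomial deviance selects lambda (the deviance-minimizing value, not the
1-SE rule), with the mixing parameter alpha = 0.5 by default. At lambda = 0
the solver reduces to the unpenalized MLE (verified against an independent
Newton–Raphson oracle to 1e-6). Continuous covariates enter linearly;
categorical covariates expand to indicators. Quasi-separation on rare-event
outcomes is handled by stopping once standardized coefficients exceed ±12,
i.e. the fit converges to a penalized solution whose predictions have
effectively saturated.

**Risk-modelling (two-stage).** Stage 1 fits baseline LCM risk without the
screening assignment; stage 2 is an *unpenalized* logistic model of the
outcome on {stage-1 linear predictor, screening, their interaction}.
Effectiveness-by-risk interactions are tested with likelihood-ratio tests on
the stage-2 scale. A published risk score (PLCOm2012, or the LLP-form
stand-in) can replace the stage-1 predictor; external scores are frozen,
never refit.

**Effect-modelling.** One penalized model with main effects, the screening
indicator, and a prespecified interaction set (default: sex, age,
pack-years, smoking status, years since quitting). The screening main
effect and the prespecified interactions carry penalty factor 0 so the
estimand is not shrunk toward the null.

**Harmonization.** Every model family is reduced to the same estimand by
marginal standardization (g-computation): predicted risks under screening
set to each arm for the whole (sub)population, then
`100 × (1 − Σp̂1/Σp̂0)`. The risk-ratio scale (not odds ratio) is used
because effectiveness is reported as a mortality reduction percentage.
Confidence intervals are percentile bootstrap over within-arm resamples.
Inside each resample the unpenalized stage-2 layer is always refit; the
penalized layer is refit at the lambda selected on the full data (full CV
re-selection is available via `refit_cv=True` but changes intervals
negligibly while multiplying cost by the fold count, so the fixed-lambda
refit is the default). The bootstrap default is B = 500; analyses in the
test suite and acceptance script use B = 100–200, which is sufficient for
95% percentile intervals at the simulation sizes used.

## Honest causal forest

Per tree: subsample without replacement, split the subsample into a
splitting half and an estimation half (honesty), grow by maximizing the
causal-tree criterion `n_L·n_R·(τ̂_L − τ̂_R)²` subject to ≥10 treated and
≥10 control per leaf, then estimate leaf effects (mean outcome difference)
on the estimation half only. A leaf whose estimation half lacks both arms
inherits the nearest sufficient ancestor's estimate. Defaults: 2000 trees,
subsample fraction 0.5, honesty fraction 0.5, mtry = ⌈√p⌉. Predictions
average leaf effects over trees; the estimand is the CATE on the absolute
risk scale. Relative effectiveness divides the mean predicted effect by the
mean observed control-arm outcome in the target population — the simplest
unbiased denominator under randomization.

Variance uses little bags: trees are grouped (default 4 per bag), each bag
shares a half-sample of the data, and the between-bag variance of bag-level
estimates minus the within-bag Monte-Carlo component estimates the sampling
variance (the finite-population correction of half-sampling without
replacement makes the between-bag dispersion target the full-sample variance
directly). Monte-Carlo diagnostics during development showed this is
well calibrated for forest means at subsample fraction 0.5, but overstates
the variance of *subgroup contrasts* roughly twofold when every tree in a
bag uses the identical sample (tree-structure variability then escapes the
within-bag correction). Contrast tests therefore use a subsample fraction
below one half (0.35 in the test suite) so trees within a bag draw distinct
subsamples; both the mean and contrast variances are then calibrated to
within a few percent. Deep trees are unnecessary for population-level
estimands, so depth-capped forests (depth 5–6) are used in the heavier
simulations.

## Missing data

k-nearest-neighbour imputation under a Gower-style distance:
range-standardized absolute differences for numeric variables, simple
matching for categoricals, averaged over the variables the incomplete record
has observed. All candidate predictors, including the LCM outcome, enter
the distance; the outcome is never imputed. The deterministic single
imputation takes the donor median (numeric) or majority (categorical, seeded
tie-break) of the k = 5 nearest complete donors. Multiple imputation
(default m = 30) samples one donor uniformly from the k nearest per missing
cell, independently per replicate — a deterministic aggregation would make
replicates identical, leaving nothing for Rubin's rules to propagate.
Pooling follows Rubin's rules (`T = W + (1 + 1/m)B`) with the
Barnard–Rubin degrees-of-freedom adjustment when a complete-data df is
supplied. The NOS sensitivity analysis reassigns non-small-cell
not-otherwise-specified cases to {ADN, SQM, OTH} by a multinomial logistic
model on participant characteristics, study arm and detection mode, drawn
m times; small-cell is never assigned.

## Benefit metrics

The C-statistic is the usual concordance (midrank ties). C-for-benefit
rank-matches CT and control records on predicted benefit 1:1, drops the
excess of the larger arm from its highest-predicted-benefit end, scores each
pair's observed benefit as `y(control) − y(CT) ∈ {−1, 0, 1}`, and computes
concordance between predicted (pair mean) and observed benefit over pairs
with differing observed benefit; it is invariant to monotone transforms of
the predictions. Calibration-for-benefit groups records by
predicted-benefit quintiles and compares group mean predicted benefit with
the observed arm contrast (risk difference on the absolute scale; one minus
the event-rate ratio, via the exact conditional-binomial machinery, on the
relative scale), summarized by a group-size-weighted least-squares line.
External validation freezes the fitted model — coefficients, standardization
constants, trees — and recomputes every metric and standardized estimate on
the other cohort; a missing covariate is an error, never a silent refit.

## Synthetic trial generator

The generator defines the study conditions for every test. Participants
draw harmonized covariates from NELSON-like (84% male, median age 58,
10-year window, unscreened control) or NLST-like (59% male, median age 60,
heavier smoking, 7-year window, radiography control) distributions. Arms
are assigned by blocked randomization stratified by 5-year age group, sex
and screening center (4 centers), block length 6 or 8.

Outcome mechanism: a logistic model gives each participant a lung-cancer
probability within the window (control-arm cumulative death risk ≈2.6%
NELSON-like, ≈2.2% NLST-like); cases draw a latent histology from a
covariate-dependent multinomial whose gradients place adenocarcinoma in
women, former smokers and light pack-year histories and small-cell/squamous
disease in heavy current smokers; stage (early/late) is drawn per
histology; screening shifts a per-histology fraction of late-stage incidence
to early stage, and death follows stage-conditional case fatality. The
requested per-histology relative mortality reduction is converted to the
implied stage-shift fraction in closed form, so the configured effect *is*
the true effect, and Fig-5-style incidence-shift tables are meaningful.
Default effects: NELSON-like {ADN 20%, SQM 50%, OTH 30%, SCLC 10%};
NLST-like {ADN 23%, SQM −28%, OTH 35%, SCLC 11%}. Because the screening
effect is purely histology-specific while histology tracks covariates,
overall effectiveness inherits covariate heterogeneity *emergently* —
females, former smokers and lighter smokers show higher overall
effectiveness under the NLST-like configuration without any
covariate-by-screening interaction in the generator, and within-histology
effectiveness shows none. Mixture gradients were fixed once, at design
time, to produce subgroup gaps of the magnitude seen in published histology
distributions (true NLST-like gaps: female−male ≈ +9pp, former−current
≈ +8pp, <30 pack-years ≈ +12pp).

Counterfactual outcomes under both arms are drawn with shared uniforms
(monotone coupling), and the sidecar ground truth carries analytic
per-record death probabilities under each arm, so the simulated estimand is
known exactly per replicate rather than approximated by Monte-Carlo.

What the generator does *not* emulate: screening-round structure, interval
cancers, contamination, nodule management, non-lung-cancer mortality
(survivors are censored at the window), correlation between age and smoking
duration, and post-baseline smoking-behaviour change. Event times are
uniform given the event, so analyses sensitive to hazard shape are outside
what passing tests demonstrate; rate, risk and CATE machinery — the
package's scope — are insensitive to this. Passing parameter-recovery tests
show the estimators are consistent and their intervals calibrated *under
this generator*, not that real-trial estimates are unbiased.

## Problem sizes used by the test suite

Simulation-heavy checks run at sizes chosen for a single CPU: parameter
recovery uses 10 replicates of a 20,000-per-arm NELSON-like trial with
bootstrap B = 150 and 200-tree depth-capped forests; cross-method
concordance uses 5 replicates at 10,000 per arm; the emergent-heterogeneity
ordering uses 20 replicates at 250,000 per arm (rate-ratio machinery only,
where large n is cheap and subgroup death counts dominate power); the
quintile pattern uses 20 replicates at 100,000 per arm with a steepened
baseline-risk gradient and a constant 30% relative effect; null calibration
uses 400 replicates at 1,200 per arm with scaled-down models. The
acceptance script runs the full pipeline at 20,000 per arm per trial, with risk-quintile benefits computed on a dedicated 100,000-per-arm simulation where the benefit gradient dominates per-quintile noise.

## Known limitations

* The LLP-form risk-model resource is a synthetic stand-in (labelled as
  such); only PLCOm2012 ships published coefficients.
* The pipeline driver analyses the first completed imputation when m > 1;
  full per-replicate analysis with Rubin pooling is available through the
  library (`multiply_impute` + `rubin_pool`) but is not wired through every
  pipeline cell.
* The median-of-bounds aggregation across methods is a presentation
  convention, not a frequentist interval, and is reported as such.
* Bootstrap intervals for penalized models hold lambda fixed by default;
  uncertainty in the penalty selection itself is not propagated unless
  `refit_cv=True`.
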
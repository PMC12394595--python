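import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from screenhet.cohort import Cohort
from screenhet.penalized import LogisticFit, newton_logistic
from screenhet.pathmodels import (build_design, fit_effect_model, fit_pooled,
                                  fit_two_stage_risk_model,
                                  lr_interaction_test,
                                  standardized_effectiveness)
from screenhet.simulate import nelson_like_config, simulate_cohort

from conftest import make_cohort


class _StubModel:
    """Counterfactual model with prescribed risk pair, for oracle checks."""

    outcome = "overall_lcm"
    method_label = "stub"

    def __init__(self, fn):
        self.fn = fn

    def predict_counterfactual(self, df):
        return self.fn(df)


class TestStandardization:
    def test_proportional_risks_give_fifty_percent(self, nelson_small):
        cohort, _ = nelson_small
        rng = np.random.default_rng(0)
        p0 = rng.uniform(0.01, 0.2, cohort.n)
        model = _StubModel(lambda df, p0=p0: (p0[: len(df)], 0.5 * p0[: len(df)]))
        est = standardized_effectiveness(model, cohort, B=0)
        assert est.relative_pct == pytest.approx(50.0)

    def test_screen_ignoring_model_gives_zero(self, nelson_small):
        cohort, _ = nelson_small
        p = np.full(cohort.n, 0.05)
        model = _StubModel(lambda df, p=p: (p[: len(df)], p[: len(df)]))
        est = standardized_effectiveness(model, cohort, B=0)
        assert est.relative_pct == pytest.approx(0.0)
        assert est.abs_per_1000 == pytest.approx(0.0)

    def test_matches_record_loop_oracle(self, nelson_small):
        cohort, _ = nelson_small
        model = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.001)
        est = standardized_effectiveness(model, cohort, B=0)
        p0, p1 = model.predict_counterfactual(cohort.records)
        s0 = sum(p0[i] for i in range(cohort.n))
        s1 = sum(p1[i] for i in range(cohort.n))
        assert est.relative_pct == pytest.approx(100 * (1 - s1 / s0))
        assert est.abs_per_1000 == pytest.approx(
            1000 * np.mean([p0[i] - p1[i] for i in range(cohort.n)]))

    def test_subgroup_restricts_standardization_population(self, nelson_small):
        cohort, _ = nelson_small
        model = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.001)
        est = standardized_effectiveness(model, cohort,
                                         subgroup=("sex", "female"), B=0)
        mask = (cohort.records["sex"] == "female").to_numpy()
        p0, p1 = model.predict_counterfactual(cohort.records)
        assert est.relative_pct == pytest.approx(
            100 * (1 - p1[mask].sum() / p0[mask].sum()))
        assert est.n == int(mask.sum())


class TestTwoStage:
    def test_stage1_never_sees_arm(self, nelson_small):
        cohort, _ = nelson_small
        model = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01)
        assert "screen" not in model.stage1.terms
        assert set(model.stage2.terms) == {"intercept", "lp", "screen",
                                           "lp_x_screen"}

    def test_screen_coefficient_zero_predicts_identical_arms(self, nelson_small):
        cohort, _ = nelson_small
        model = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01)
        s2 = model.stage2
        forced = LogisticFit(terms=s2.terms,
                             coef=np.array([s2.coef[0], s2.coef[1], 0.0, 0.0]),
                             loglik=s2.loglik, cov=s2.cov, n=s2.n)
        model.stage2 = forced
        p0, p1 = model.predict_counterfactual(cohort.records)
        assert np.allclose(p0, p1)

    def test_homogeneous_odds_effect_gives_null_interaction(self):
        """Constant odds-ratio screening effect: stage-2 interaction ~ 0."""
        rng = np.random.default_rng(5)
        n = 30000
        age = rng.normal(60, 5, n)
        screen = (np.arange(n) % 2 == 0).astype(float)
        lp = -3.5 + 0.08 * (age - 60) - 0.5 * screen
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        s2 = newton_logistic(
            np.column_stack([0.08 * (age - 60), screen,
                             0.08 * (age - 60) * screen]), y,
            terms=["lp", "screen", "lp_x_screen"])
        se = np.sqrt(np.diag(s2.cov))[3]
        assert abs(s2.coef[3]) < 3 * se

    def test_external_scores_skip_stage1(self, nelson_small):
        cohort, _ = nelson_small
        lp = np.log(np.clip(
            cohort.records["pack_years"].to_numpy() / 1000, 1e-4, 0.5))
        model = fit_two_stage_risk_model(cohort, external_lp=lp,
                                         external_label="toy")
        assert model.stage1 is None
        assert model.method_label == "risk_model[toy]"
        est = standardized_effectiveness(model, cohort, B=20, seed=3)
        assert np.isfinite(est.relative_pct)


class TestLRTest:
    def test_identical_models_give_zero_statistic(self, nelson_small):
        cohort, _ = nelson_small
        m = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01)
        stat, df, p = lr_interaction_test(m, m)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_matches_likelihood_oracle(self, nelson_small):
        cohort, _ = nelson_small
        full = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01,
                                        interaction=True)
        red = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01,
                                       interaction=False)
        stat, df, p = lr_interaction_test(full, red)
        # brute-force likelihood evaluation through statsmodels
        lp = full.baseline_lp(cohort.records)
        screen = (cohort.records["arm"] == "CT").to_numpy(float)
        y = cohort.records["lc_death"].astype(bool).to_numpy(float)
        llf = sm.Logit(y, sm.add_constant(
            np.column_stack([lp, screen, lp * screen]))).fit(disp=0).llf
        llr = sm.Logit(y, sm.add_constant(
            np.column_stack([lp, screen]))).fit(disp=0).llf
        assert df == 1
        assert stat == pytest.approx(2 * (llf - llr), abs=1e-4)

    def test_non_nested_models_rejected(self, nelson_small):
        cohort, _ = nelson_small
        a = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.01,
                                     interaction=False)
        rng = np.random.default_rng(0)
        other = newton_logistic(rng.normal(size=(cohort.n, 2)),
                                cohort.records["lc_death"].astype(float),
                                terms=["u", "v"])
        with pytest.raises(ValueError, match="not nested"):
            lr_interaction_test(a, other)


class TestEffectModel:
    def test_screen_terms_unpenalized(self, nelson_small):
        cohort, _ = nelson_small
        m = fit_effect_model(cohort, seed=0, lambda_=0.05)
        pf = m.base.penalty_factor
        assert pf["screen"] == 0.0
        assert all(pf[t] == 0.0 for t in pf if t.startswith("screen:"))

    def test_empty_interaction_set_reduces_to_main_effects(self, nelson_small):
        cohort, _ = nelson_small
        m = fit_effect_model(cohort, interaction_set=(), seed=0, lambda_=0.02)
        assert [t for t in m.base.terms if t.startswith("screen:")] == []
        # equivalent to an elastic net on main effects + screen
        from screenhet.penalized import fit_elastic_net_logistic
        X = build_design(cohort.records, m.covariates)
        X["screen"] = (cohort.records["arm"] == "CT").to_numpy(float)
        direct = fit_elastic_net_logistic(
            X, cohort.records["lc_death"].astype(float), lambda_=0.02,
            penalty_factor={"screen": 0.0})
        for t in m.base.terms:
            assert m.base.coefficients[t] == pytest.approx(
                direct.coefficients[t], abs=1e-7)

    def test_missing_interaction_covariate_rejected(self, nelson_small):
        cohort, _ = nelson_small
        with pytest.raises(ValueError, match="nonexistent"):
            fit_effect_model(cohort, interaction_set=("nonexistent",),
                             lambda_=0.02)

    def test_null_interactions_shrink_toward_zero(self):
        """With no true interactions the prespecified interaction terms stay
        small relative to the screening main effect."""
        cohort, _ = simulate_cohort(nelson_like_config(
            n_per_arm=4000, seed=21,
            screening_effect={"ADN": 0.25, "SQM": 0.25, "OTH": 0.25,
                              "SCLC": 0.25}))
        m = fit_effect_model(cohort, interaction_set=("sex", "smoking_status"),
                             seed=0)
        inter = [abs(v) for t, v in m.base.coefficients.items()
                 if t.startswith("screen:")]
        assert max(inter) < 1.0


class TestPooled:
    def test_pooling_cohort_with_itself_reproduces_estimates(self, nelson_small):
        cohort, _ = nelson_small
        single = fit_two_stage_risk_model(cohort, seed=0, lambda_=0.005)
        pooled = fit_pooled([cohort, cohort], kind="risk", seed=0,
                            lambda_=0.005)
        e1 = standardized_effectiveness(single, cohort, B=0)
        ep = standardized_effectiveness(
            pooled, Cohort(pooled.stage1 and cohort.records, cohort.trial,
                           cohort.followup_cap), B=0)
        assert ep.relative_pct == pytest.approx(e1.relative_pct, abs=1e-6)

    def test_exchangeable_trials_have_null_trial_coefficient(self):
        a, _ = simulate_cohort(nelson_like_config(n_per_arm=3000, seed=31))
        b, _ = simulate_cohort(nelson_like_config(n_per_arm=3000, seed=32))
        b = Cohort(b.records.assign(trial="SYNTH-B"), "SYNTH-B", b.followup_cap)
        model = fit_pooled([a, b], kind="risk", seed=0, lambda_=1e-4)
        coef = model.stage1.coefficients.get("trial=SYNTH-NELSON", 0.0)
        assert abs(coef) < 0.25

    def test_schema_mismatch_listed(self, nelson_small):
        cohort, _ = nelson_small
        other = Cohort(cohort.records.drop(columns=["bmi"]), "X", 10.0)
        with pytest.raises(ValueError, match="bmi"):
            fit_pooled([cohort, other])
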
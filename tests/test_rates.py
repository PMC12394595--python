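import math

import numpy as np
import pytest
from scipy import stats

from screenhet.cohort import categorize_covariates
from screenhet.rates import (benjamini_hochberg, exact_rate_ratio,
                             histology_distribution, rate_difference,
                             stage_histology_table, subgroup_table,
                             overall_table)

from conftest import make_cohort


def brute_force_exact(events_ct, py_ct, events_ctrl, py_ctrl, alpha=0.05):
    """Independent oracle: explicit conditional-binomial enumeration."""
    T = events_ct + events_ctrl
    p0 = py_ct / (py_ct + py_ctrl)
    pmf = np.array([math.comb(T, k) * p0 ** k * (1 - p0) ** (T - k)
                    for k in range(T + 1)])
    lower = pmf[: events_ct + 1].sum()
    upper = pmf[events_ct:].sum()
    return min(1.0, 2.0 * min(lower, upper))


class TestExactRateRatio:
    def test_symmetric_inputs_give_null(self):
        c = exact_rate_ratio(10, 1000.0, 10, 1000.0)
        assert c.rate_ratio == pytest.approx(1.0)
        assert c.p_value == pytest.approx(1.0)
        assert c.relative_effectiveness_pct == pytest.approx(0.0)

    def test_half_rate_worked_example(self):
        # 5 vs 10 events on equal person-time: p = 2 P(X <= 5), X ~ Bin(15, .5)
        c = exact_rate_ratio(5, 1000.0, 10, 1000.0)
        assert c.rate_ratio == pytest.approx(0.5)
        assert c.p_value == pytest.approx(2 * stats.binom.cdf(5, 15, 0.5))
        assert c.p_value == pytest.approx(0.302, abs=5e-4)
        assert c.relative_effectiveness_pct == pytest.approx(50.0)

    def test_matches_enumeration_for_small_totals(self):
        for total in range(1, 13):
            for x in range(total + 1):
                got = exact_rate_ratio(x, 800.0, total - x, 800.0)
                want = brute_force_exact(x, 800.0, total - x, 800.0)
                assert got.p_value == pytest.approx(want, abs=1e-12), (x, total)

    def test_unequal_person_time_matches_enumeration(self):
        got = exact_rate_ratio(4, 1500.0, 9, 700.0)
        want = brute_force_exact(4, 1500.0, 9, 700.0)
        assert got.p_value == pytest.approx(want, abs=1e-12)

    def test_ci_contains_estimate_and_inverts_test(self):
        c = exact_rate_ratio(7, 1200.0, 15, 1100.0)
        lo, hi = c.rr_ci
        assert lo < c.rate_ratio < hi
        # Clopper-Pearson inversion: tail probability at each limit = alpha/2
        T = 22
        p_lo = (lo * 1200.0) / (lo * 1200.0 + 1100.0)
        p_hi = (hi * 1200.0) / (hi * 1200.0 + 1100.0)
        assert stats.binom.sf(6, T, p_lo) == pytest.approx(0.025, abs=1e-10)
        assert stats.binom.cdf(7, T, p_hi) == pytest.approx(0.025, abs=1e-10)

    def test_zero_events_both_arms_flagged(self):
        c = exact_rate_ratio(0, 1000.0, 0, 1000.0)
        assert math.isnan(c.rate_ratio)
        assert c.rr_ci == (0.0, math.inf)
        assert c.flagged

    def test_zero_control_events_infinite_upper(self):
        c = exact_rate_ratio(3, 1000.0, 0, 1000.0)
        assert math.isinf(c.rate_ratio)
        assert math.isinf(c.rr_ci[1])

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_rate_ratio(-1, 1000.0, 2, 1000.0)
        with pytest.raises(ValueError):
            exact_rate_ratio(1, 0.0, 2, 1000.0)


class TestRateDifference:
    def test_arithmetic(self):
        c = rate_difference(5, 1000.0, 10, 1000.0)
        assert c.rate_diff_per_1000 == pytest.approx(-5.0)

    def test_equal_rates_symmetric_ci(self):
        c = rate_difference(8, 1000.0, 8, 1000.0)
        assert c.rate_diff_per_1000 == pytest.approx(0.0)
        assert c.rd_ci[0] == pytest.approx(-c.rd_ci[1])

    def test_ci_half_width_closed_form(self):
        c = rate_difference(12, 1500.0, 20, 1800.0)
        se = math.sqrt(12 / 1500.0 ** 2 + 20 / 1800.0 ** 2)
        half = stats.norm.ppf(0.975) * se * 1000.0
        assert (c.rd_ci[1] - c.rd_ci[0]) / 2 == pytest.approx(half)


class TestSubgroupTables:
    def test_identical_levels_identical_comparisons(self):
        co = make_cohort(
            8,
            sex=["male", "male", "female", "female"] * 2,
            arm=["CT", "control"] * 4,
            lc_diagnosis=[True, True, True, True, False, False, False, False],
            lc_diagnosis_time=[2.0, 2.0, 2.0, 2.0] + [np.nan] * 4,
            histology=["ADN"] * 4 + ["none"] * 4,
            stage_group=["late"] * 4 + ["none"] * 4,
            detection_mode=["screen"] * 4 + ["none"] * 4,
            lc_death=[True, True, True, True, False, False, False, False],
            lc_death_time=[5.0, 5.0, 5.0, 5.0] + [np.nan] * 4)
        tab = subgroup_table(co, "sex")
        rows = tab.set_index("subgroup_level")
        assert rows.loc["male", "estimate_pct"] == \
            pytest.approx(rows.loc["female", "estimate_pct"])

    def test_sex_rows_pool_to_overall_events(self, nelson_small):
        cohort, _ = nelson_small
        tab = subgroup_table(cohort, "sex")
        overall = overall_table(cohort).iloc[0]
        known = tab[tab["subgroup_level"].isin(["male", "female"])]
        n_unknown = (cohort.records["sex"] == "unknown").sum()
        assert known["events_ct"].sum() + known["events_ctrl"].sum() \
            + 0 * n_unknown <= overall["events_ct"] + overall["events_ctrl"]
        if n_unknown == 0:
            assert known["events_ct"].sum() == overall["events_ct"]

    def test_histology_rows_partition_deaths(self, nelson_small):
        cohort, _ = nelson_small
        df = cohort.records
        total = 0
        for h in ("ADN", "SQM", "OTH", "SCLC"):
            row = overall_table(cohort, outcome=("lcm", h)).iloc[0]
            total += row["events_ct"] + row["events_ctrl"]
        known_deaths = (df["lc_death"].astype(bool)
                        & df["histology"].isin(["ADN", "SQM", "OTH", "SCLC"])).sum()
        assert total == known_deaths

    def test_stage_histology_differences_sum_over_stage(self, nelson_small):
        cohort, _ = nelson_small
        tab = stage_histology_table(cohort)
        for h in ("ADN", "SQM", "OTH", "SCLC"):
            sub = tab[tab["histology"] == h].set_index("stage")
            assert sub.loc["early", "rate_diff_per_1000"] \
                + sub.loc["late", "rate_diff_per_1000"] == pytest.approx(
                    sub.loc["all", "rate_diff_per_1000"], abs=1e-9)


class TestHistologyDistribution:
    def test_rows_sum_to_one(self, nelson_small):
        cohort, _ = nelson_small
        cohort = categorize_covariates(cohort, {"pack_years": [30, 40, 50]})
        tab = histology_distribution(cohort, "pack_years_group", arm="CT")
        sums = tab[["ADN", "SQM", "OTH", "SCLC"]].sum(axis=1)
        assert np.allclose(sums[tab["n_cases"] > 0], 1.0)

    def test_degenerate_all_adn(self):
        co = make_cohort(
            4, lc_diagnosis=[True] * 4,
            lc_diagnosis_time=[2.0] * 4, histology=["ADN"] * 4,
            stage_group=["early"] * 4, detection_mode=["screen"] * 4)
        tab = histology_distribution(co)
        assert tab.iloc[0][["ADN", "SQM", "OTH", "SCLC"]].tolist() == \
            [1.0, 0.0, 0.0, 0.0]

    def test_mixture_gradient_matches_generator(self, nelson_mid):
        """ADN share falls and SCLC share rises with pack-years among cases,
        as the configured mixture prescribes."""
        cohort, truth = nelson_mid
        co = categorize_covariates(cohort, {"pack_years": [30, 50]})
        merged = co.records.join(truth.frame[["latent_histology"]])
        cases = merged[merged["lc_diagnosis"].astype(bool)]
        shares = (cases.groupby("pack_years_group")["latent_histology"]
                  .value_counts(normalize=True).unstack())
        assert shares.loc["<30", "ADN"] > shares.loc[">50", "ADN"]
        assert shares.loc["<30", "SCLC"] < shares.loc[">50", "SCLC"]


def test_benjamini_hochberg_matches_statsmodels_ordering():
    p = [0.001, 0.02, 0.04, 0.2, 0.5, np.nan]
    adj = benjamini_hochberg(p)
    assert np.isnan(adj[-1])
    assert np.all(np.diff(adj[:-1][np.argsort(p[:-1])]) >= -1e-12)
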
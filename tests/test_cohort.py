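import numpy as np
import pandas as pd
import pytest

from screenhet.cohort import (Cohort, CohortError, SchemaError,
                              apply_eligibility_filters, categorize_covariates,
                              load_cohort, person_years, truncate_follow_up,
                              write_cohort)

from conftest import make_cohort, make_records


class TestLoadWrite:
    def test_three_row_csv_round_trips(self, tmp_path):
        co = make_cohort(4)
        path = tmp_path / "c.csv"
        write_cohort(co, path)
        back = load_cohort(path)
        assert back.n == 4
        assert back.rejected == []
        pd.testing.assert_frame_equal(
            back.records.reset_index(drop=True), co.records,
            check_dtype=False)

    def test_write_load_identity_on_simulated_cohort(self, tmp_path, nelson_small):
        cohort, _ = nelson_small
        path = tmp_path / "sim.csv"
        write_cohort(cohort, path)
        back = load_cohort(path)
        assert back.rejected == []
        assert back.n == cohort.n
        a = back.records.reset_index(drop=True)
        b = cohort.records.reset_index(drop=True)
        for col in a.columns:
            pd.testing.assert_series_equal(a[col], b[col], check_dtype=False,
                                           obj=col)

    def test_death_without_diagnosis_rejected_with_row_diagnostic(self, tmp_path):
        df = make_records(4)
        df.loc[1, "lc_death"] = True
        df.loc[1, "lc_death_time"] = 3.0
        path = tmp_path / "bad.csv"
        write_cohort(Cohort(df), path)
        back = load_cohort(path)
        assert back.n == 3
        assert any(i.row_id == "P001" and "lc_death" in i.field
                   for i in back.rejected)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        df = make_records(3).drop(columns=["arm"])
        path = tmp_path / "noarm.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="arm"):
            load_cohort(path)

    def test_validate_rejects_duplicate_ids(self):
        co = make_cohort(4, id=["A", "A", "B", "C"])
        with pytest.raises(CohortError, match="duplicate"):
            co.validate()


class TestEligibility:
    def test_prior_lc_rule_counts(self):
        df = make_records(10)
        for i in (2, 5):
            df.loc[i, ["lc_diagnosis", "histology", "stage_group"]] = \
                [True, "ADN", "early"]
            df.loc[i, "lc_diagnosis_time"] = -1.0
        co = Cohort(df)
        out, logs = apply_eligibility_filters(co, ["prior_lc"])
        assert out.n == 8
        assert logs[0].rule == "prior_lc" and logs[0].n_removed == 2
        assert set(logs[0].ids) == {"P002", "P005"}

    def test_clean_cohort_unchanged_with_zero_logs(self):
        co = make_cohort(6)
        out, logs = apply_eligibility_filters(
            co, ["never_smoker", "prior_lc", "missing_incidence_date"])
        assert out.n == 6
        assert all(l.n_removed == 0 for l in logs)

    def test_filters_idempotent(self, nelson_small):
        cohort, _ = nelson_small
        df = cohort.records.copy()
        df.loc[df.index[:5], "smoking_status"] = "never"
        once, logs1 = apply_eligibility_filters(Cohort(df), ["never_smoker"])
        twice, logs2 = apply_eligibility_filters(once, ["never_smoker"])
        assert logs1[0].n_removed == 5
        assert logs2[0].n_removed == 0
        assert twice.n == once.n

    def test_unknown_rule_is_configuration_error(self):
        with pytest.raises(ValueError, match="unknown eligibility rule"):
            apply_eligibility_filters(make_cohort(4), ["bogus_rule"])


class TestTruncation:
    def test_death_beyond_cap_reset(self):
        co = make_cohort(
            2,
            lc_diagnosis=[True, False], lc_diagnosis_time=[6.0, np.nan],
            histology=["ADN", "none"], stage_group=["late", "none"],
            detection_mode=["clinical", "none"],
            lc_death=[True, False], lc_death_time=[8.0, np.nan],
            followup_years=[8.0, 10.0])
        out = truncate_follow_up(co, 7.0)
        row = out.records.iloc[0]
        assert not row["lc_death"] and np.isnan(row["lc_death_time"])
        assert row["lc_diagnosis"]  # diagnosis at year 6 survives the cap
        assert out.records["followup_years"].tolist() == [7.0, 7.0]

    def test_cap_above_max_followup_is_identity(self, nelson_small):
        cohort, _ = nelson_small
        out = truncate_follow_up(cohort, 99.0)
        pd.testing.assert_frame_equal(out.records, cohort.records)

    def test_event_totals_monotone_in_cap(self, nelson_small):
        cohort, _ = nelson_small
        deaths = [truncate_follow_up(cohort, cap).records["lc_death"].sum()
                  for cap in (3.0, 5.0, 7.0, 10.0)]
        assert deaths == sorted(deaths)

    def test_composition_equals_min_cap(self, nelson_small):
        cohort, _ = nelson_small
        ab = truncate_follow_up(truncate_follow_up(cohort, 8.0), 5.0)
        direct = truncate_follow_up(cohort, 5.0)
        pd.testing.assert_frame_equal(ab.records, direct.records)
        assert ab.followup_cap == 5.0

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            truncate_follow_up(make_cohort(4), 0.0)


class TestPersonYears:
    def test_simple_sum(self):
        co = make_cohort(2, followup_years=[5.0, 7.0])
        tab = person_years(co)
        assert tab["person_years"].sum() == pytest.approx(12.0)

    def test_grouping_partitions_totals(self, nelson_small):
        cohort, _ = nelson_small
        total = person_years(cohort)
        by_sex = person_years(cohort, by=["sex"])
        assert by_sex["person_years"].sum() == pytest.approx(
            total["person_years"].sum())
        assert by_sex["events"].sum() == total["events"].sum()

    def test_matches_record_loop_oracle(self, nelson_small):
        cohort, _ = nelson_small
        tab = person_years(cohort, by=["smoking_status"])
        df = cohort.records
        for _, row in tab.iterrows():
            exp_py = 0.0
            exp_ev = 0
            for _, r in df[(df["smoking_status"] == row["smoking_status"])
                           & (df["arm"] == row["arm"])].iterrows():
                if r["lc_death"]:
                    exp_py += r["lc_death_time"]
                    exp_ev += 1
                else:
                    exp_py += r["followup_years"]
            assert row["person_years"] == pytest.approx(exp_py)
            assert row["events"] == exp_ev

    def test_unknown_grouping_variable_named_in_error(self):
        with pytest.raises(ValueError, match="shoe_size"):
            person_years(make_cohort(4), by=["shoe_size"])


class TestCategorize:
    def test_boundary_conventions(self):
        co = make_cohort(4, pack_years=[29.9, 30.0, 49.9, 50.0])
        out = categorize_covariates(co, {"pack_years": [30, 40, 50]})
        assert out.records["pack_years_group"].tolist() == \
            ["<30", "30–39", "40–49", ">50"]

    def test_counts_match_brute_force_binning(self, nelson_small):
        cohort, _ = nelson_small
        cuts = [30, 40, 50]
        out = categorize_covariates(cohort, {"pack_years": cuts})
        got = out.records["pack_years_group"].value_counts()
        vals = cohort.records["pack_years"].to_numpy()
        expected = {"<30": int((vals < 30).sum()),
                    "30–39": int(((vals >= 30) & (vals < 40)).sum()),
                    "40–49": int(((vals >= 40) & (vals < 50)).sum()),
                    ">50": int((vals >= 50).sum())}
        assert {k: int(v) for k, v in got.items()} == \
            {k: v for k, v in expected.items() if v}

    def test_non_monotone_breaks_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            categorize_covariates(make_cohort(4), {"pack_years": [40, 30]})

    def test_original_column_retained(self):
        out = categorize_covariates(make_cohort(4), {"age": [60]})
        assert "age" in out.records.columns
        assert "age_group" in out.records.columns


def test_row_order_permutation_invariance(nelson_small):
    """Filtering, truncation and categorization commute with row order."""
    cohort, _ = nelson_small
    rng = np.random.default_rng(0)
    perm = rng.permutation(cohort.n)
    shuffled = Cohort(cohort.records.iloc[perm].reset_index(drop=True),
                      cohort.trial, cohort.followup_cap)

    def process(c):
        c, _ = apply_eligibility_filters(c, ["prior_lc"])
        c = truncate_follow_up(c, 7.0)
        c = categorize_covariates(c, {"pack_years": [30, 40, 50]})
        return c.records.sort_values("id").reset_index(drop=True)

    pd.testing.assert_frame_equal(process(cohort), process(shuffled))
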
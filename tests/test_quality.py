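"""Quality evaluation: loss accounting, characterization, coverage, checks."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mimic2omop import (GeneratorConfig, SourceDatabase, characterize,
                        compare_characterizations, compute_loss,
                        generate_source, heel_checks, mapping_coverage,
                        run_etl)
from mimic2omop.quality import load_mapping_spec, _round_half_up

SMALL = dict(mean_labs_per_admission=10.0, mean_drugs_per_admission=4.0,
             mean_chart_events_per_admission=10.0)


class TestLoss:
    def test_column_loss_matches_hand_count_from_spec(self, small_result):
        spec = load_mapping_spec()
        loss = compute_loss(small_result.report).set_index("source_table")
        # hand count: chartevents has 15 columns, 6 of status 'dropped'
        ce = spec[spec["source_table"] == "chartevents"]
        assert len(ce) == 15
        assert (ce["status"] == "dropped").sum() == 6
        assert loss.loc["chartevents", "columns_lost_pct"] == 40.0

    def test_zero_error_fraction_zero_row_loss_in_transformed_tables(
            self, small_result):
        loss = compute_loss(small_result.report).set_index("source_table")
        transformed = loss.drop(index="icustays")
        assert (transformed["rows_lost_pct"] == 0).all()
        # the stay table is derivable from transfers and is not transformed
        assert loss.loc["icustays", "rows_lost_pct"] == 100.0

    def test_injected_flags_reported_exactly(self):
        db = generate_source(GeneratorConfig(
            n_patients=50, seed=9, error_row_fraction=0.1, **SMALL))
        flagged_counts = db.table_flag_counts()
        res = run_etl(db)
        loss = compute_loss(res.report).set_index("source_table")
        for table, n_flagged in flagged_counts.items():
            inp = res.report.input_rows[table]
            want = _round_half_up(100.0 * n_flagged / inp, 4) if inp else 0.0
            assert loss.loc[table, "rows_lost_pct"] == want, table

    def test_unknown_table_in_report_rejected(self, small_result):
        rep = copy.deepcopy(small_result.report)
        rep.input_rows["no_such_table"] = 5
        with pytest.raises(ValueError, match="no_such_table"):
            compute_loss(rep)


class TestCharacterize:
    def test_empty_database_all_zero(self):
        c = characterize(SourceDatabase())
        assert c.items["persons"] == 0
        assert c.items["admissions"] == 0

    def test_female_share_recovered_within_binomial_interval(self):
        db = generate_source(GeneratorConfig(
            n_patients=2000, seed=31, female_fraction=0.44, **SMALL))
        c = characterize(db)
        lo = stats.binom.ppf(0.005, 2000, 0.44)
        hi = stats.binom.ppf(0.995, 2000, 0.44)
        assert lo <= c.items["female_n"] <= hi

    def test_los_quantiles_linear_interpolation(self):
        db = SourceDatabase()
        db["patients"] = pd.DataFrame([
            dict(row_id=i, subject_id=i, gender="F",
                 dob=pd.Timestamp("2050-01-01")) for i in (1, 2, 3)])
        db["admissions"] = pd.DataFrame([
            dict(row_id=i, subject_id=i, hadm_id=100 + i,
                 admittime=pd.Timestamp("2101-01-01"),
                 dischtime=pd.Timestamp("2101-01-01")
                 + pd.Timedelta(days=d), admission_type="EMERGENCY",
                 hospital_expire_flag=0)
            for i, d in [(1, 1), (2, 2), (3, 9)]])
        c = characterize(db)
        assert c.items["hospital_los_median_days"] == 2.0
        assert c.items["hospital_los_q1"] == 1.5
        assert c.items["hospital_los_q3"] == 5.5

    def test_invariant_under_row_shuffling(self, small_source):
        shuffled = small_source.copy()
        for name, df in shuffled.tables.items():
            shuffled.tables[name] = df.sample(
                frac=1.0, random_state=5).reset_index(drop=True)
        a = characterize(small_source).to_dict()
        b = characterize(shuffled).to_dict()
        assert a == b

    def test_obfuscated_ages_counted_in_oldest_band_not_mean(self):
        db = generate_source(GeneratorConfig(n_patients=500, seed=3,
                                             **SMALL))
        c = characterize(db)
        assert c.items["obfuscated_age_n"] > 0
        assert c.items["mean_age_years"] < 100
        band_total = sum(c.items[f"age_band_{b}_n"]
                         for b in ("0-5", "6-15", "16-25", "26-45",
                                   "46-65", "66-80", ">80"))
        assert band_total == c.items["admissions"]


class TestComparison:
    def test_identical_characterizations_all_equal(self, small_source):
        c = characterize(small_source)
        diff = compare_characterizations(c, c)
        assert set(diff["status"]) <= {"equal", "missing"}

    def test_source_vs_cdm_invariants_exactly_equal(self, small_source,
                                                    small_result):
        diff = compare_characterizations(characterize(small_source),
                                         characterize(small_result.cdm))
        from mimic2omop.quality import INVARIANT_ITEMS
        inv = diff[diff["item"].isin(INVARIANT_ITEMS)]
        assert (inv["status"] == "equal").all(), \
            inv[inv["status"] != "equal"]

    def test_cdm_icu_count_below_source_flags_violation(self, small_source):
        a = characterize(small_source)
        b = copy.deepcopy(a)
        b.items["icu_stays"] = a.items["icu_stays"] - 1
        diff = compare_characterizations(a, b).set_index("item")
        assert diff.loc["icu_stays", "status"] == "violation"

    def test_merge_free_model_never_undercounts_stays(self, small_source,
                                                      small_result):
        diff = compare_characterizations(
            characterize(small_source),
            characterize(small_result.cdm)).set_index("item")
        assert diff.loc["icu_stays", "status"] in ("equal",
                                                   "within_tolerance")


class TestCoverage:
    def test_declared_rounding_rule(self):
        # 787 of 1035 concepts = 76.04 -> 76 under round half up
        assert _round_half_up(100.0 * 787 / 1035) == 76.0
        assert _round_half_up(0.5) == 1.0

    def test_fixture_fraction_reproduced(self, small_result):
        cdm = copy.deepcopy(small_result.cdm)
        rows = pd.DataFrame({
            "condition_occurrence_id": np.arange(1035),
            "person_id": small_result.cdm["person"]["person_id"].iloc[0],
            "condition_concept_id": [320128] * 787 + [0] * 248,
            "condition_start_datetime": pd.Timestamp("2101-01-01"),
            "condition_type_concept_id": 32817,
            "condition_source_value": [f"code{i}" for i in range(1035)],
            "condition_source_concept_id": 0})
        cdm.tables["condition_occurrence"] = rows
        cov = mapping_coverage(cdm).set_index("table")
        assert cov.loc["CONDITION_OCCURRENCE",
                       "mapped_source_concepts_pct"] == 76.0
        assert cov.loc["CONDITION_OCCURRENCE", "source_concepts_n"] == 1035

    def test_fully_mapped_table_reports_100(self, small_result):
        cov = mapping_coverage(small_result.cdm).set_index("table")
        assert cov.loc["CARE_SITE", "mapped_records_pct"] == 100.0
        assert cov.loc["CARE_SITE", "mapped_source_concepts_pct"] == 100.0

    def test_mapped_never_exceeds_total(self, small_result):
        cov = mapping_coverage(small_result.cdm)
        assert (cov["mapped_records_n"] <= cov["records_n"]).all()
        assert (cov["mapped_source_concepts_n"]
                <= cov["source_concepts_n"]).all()


class TestHeelChecks:
    def test_clean_synthetic_run_has_zero_errors(self, small_result):
        findings = heel_checks(small_result.cdm)
        assert [f for f in findings if f.severity == "error"] == []

    def test_planted_measurement_before_birth_fires_once(self, small_result):
        cdm = copy.deepcopy(small_result.cdm)
        cdm.tables["measurement"].loc[0, "measurement_datetime"] = \
            pd.Timestamp("1700-01-01")  # before even obfuscated births
        findings = {f.check: f for f in heel_checks(cdm)}
        assert findings["event_before_birth"].count == 1
        assert findings["event_before_birth"].severity == "error"

    def test_dangling_person_fires_integrity_and_heel(self, small_result):
        cdm = copy.deepcopy(small_result.cdm)
        cdm.tables["person"] = cdm.tables["person"].iloc[1:]
        assert any("person" in v for v in cdm.integrity_violations())
        findings = {f.check for f in heel_checks(cdm)
                    if f.severity == "error"}
        assert "measurement_without_person" in findings

    def test_duplicate_primary_key_detected(self, small_result):
        cdm = copy.deepcopy(small_result.cdm)
        meas = cdm.tables["measurement"]
        meas.loc[1, "measurement_id"] = meas["measurement_id"].iloc[0]
        findings = {f.check for f in heel_checks(cdm)}
        assert "duplicate_primary_key_measurement" in findings

    def test_obfuscated_ages_reported_as_notification(self,
                                                      acceptance_result):
        findings = {f.check: f for f in heel_checks(acceptance_result.cdm)}
        f = findings.get("age_over_150_obfuscated")
        assert f is not None and f.severity == "notification"
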
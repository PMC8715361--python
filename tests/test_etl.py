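"""Structural ETL: sequence, filtering, table flows, provenance, integrity."""

import numpy as np
import pandas as pd
import pytest

from mimic2omop import (GeneratorConfig, GlobalSequence, SourceDatabase,
                        allocate_id, filter_invalid, generate_source,
                        inject_error_flags, run_etl)
from mimic2omop.etl import EtlIntegrityError
from mimic2omop.schemas import CDM_PRIMARY_KEYS, CDM_TABLES

T = pd.Timestamp


class TestGlobalSequence:
    def test_fresh_sequence_starts_at_zero(self):
        assert allocate_id(GlobalSequence()) == 0

    def test_three_calls_count_up(self):
        seq = GlobalSequence()
        assert [allocate_id(seq) for _ in range(3)] == [0, 1, 2]

    def test_bulk_take_continues_the_stream(self):
        seq = GlobalSequence()
        a = seq.take(3)
        b = allocate_id(seq)
        assert list(a) == [0, 1, 2] and b == 3

    def test_ids_globally_disjoint_across_tables(self, small_result):
        ids = small_result.cdm.sequence_ids()
        assert len(ids) == len(set(ids))

    def test_ids_monotone_in_emission_order(self, small_result):
        for name, pk in CDM_PRIMARY_KEYS.items():
            if pk is None or name in ("concept", "death"):
                continue
            col = small_result.cdm[name][pk].to_numpy()
            assert (np.diff(col) > 0).all(), name


class TestFilterInvalid:
    def test_flagged_rows_dropped(self):
        df = pd.DataFrame({"error": [1, 0, 1, 0, 1, 0, 0, 0, 0, 0]})
        kept, dropped = filter_invalid(df, "chartevents")
        assert (len(kept), len(dropped)) == (7, 3)

    def test_unflagged_table_passes_through(self):
        df = pd.DataFrame({"value": [1, 2, 3]})
        kept, dropped = filter_invalid(df, "labevents")
        assert len(kept) == 3 and len(dropped) == 0

    def test_status_string_dialect(self):
        df = pd.DataFrame({"statusdescription":
                           ["FinishedRunning", "Rewritten", "Rewritten"]})
        kept, dropped = filter_invalid(df, "inputevents_mv")
        assert (len(kept), len(dropped)) == (1, 2)

    def test_dropped_fraction_equals_flagged_fraction(self, small_source):
        flagged = inject_error_flags(small_source, 0.1, seed=5)
        counts = flagged.table_flag_counts()
        result = run_etl(flagged)
        for table, n_flagged in counts.items():
            assert result.report.dropped.get(table, {}).get(
                "flagged_invalid", 0) == n_flagged, table


class TestPersonAndVisits:
    def test_one_person_per_patient(self, small_source, small_result):
        assert len(small_result.cdm["person"]) \
            == len(small_source["patients"])

    def test_one_visit_per_admission(self, small_source, small_result):
        assert len(small_result.cdm["visit_occurrence"]) \
            == len(small_source["admissions"])

    def test_one_observation_period_per_patient_with_admissions(
            self, small_source, small_result):
        expected = small_source["admissions"]["subject_id"].nunique()
        assert len(small_result.cdm["observation_period"]) == expected

    def test_latest_admission_ethnicity_wins(self):
        db = _manual_source()
        db["admissions"].loc[0, "ethnicity"] = "ASIAN"
        db["admissions"].loc[1, "ethnicity"] = "WHITE"
        res = run_etl(db)
        person = res.cdm["person"]
        assert person.loc[person["person_source_value"] == "1",
                          "race_concept_id"].iloc[0] == 8527  # White

    def test_empty_source_yields_empty_cdm(self):
        res = run_etl(SourceDatabase())
        assert len(res.cdm["person"]) == 0
        assert len(res.cdm["visit_occurrence"]) == 0
        assert res.report.input_rows["patients"] == 0

    def test_death_count_matches_patients_with_death_date(
            self, small_source, small_result):
        expected = small_source["patients"]["dod"].notna().sum()
        assert len(small_result.cdm["death"]) == expected

    def test_gender_concepts_standard(self, small_result):
        assert set(small_result.cdm["person"]["gender_concept_id"]) \
            <= {8507, 8532}


def _manual_source() -> SourceDatabase:
    """Two patients with hand-written admissions and transfers."""
    db = SourceDatabase()
    db["patients"] = pd.DataFrame([
        dict(row_id=1, subject_id=1, gender="F",
             dob=T("2050-01-01"), dod=None, dod_hosp=None, expire_flag=0),
        dict(row_id=2, subject_id=2, gender="M",
             dob=T("2060-01-01"), dod=None, dod_hosp=None, expire_flag=0)])
    db["admissions"] = pd.DataFrame([
        dict(row_id=1, subject_id=1, hadm_id=10,
             admittime=T("2101-01-01 10:00"),
             dischtime=T("2101-01-10 10:00"),
             admission_type="EMERGENCY", ethnicity="ASIAN",
             edregtime=T("2101-01-01 06:00"),
             edouttime=T("2101-01-01 10:00"), hospital_expire_flag=0),
        dict(row_id=2, subject_id=1, hadm_id=11,
             admittime=T("2101-03-01 08:00"),
             dischtime=T("2101-03-05 08:00"),
             admission_type="ELECTIVE", ethnicity="WHITE",
             hospital_expire_flag=0),
        dict(row_id=3, subject_id=2, hadm_id=12,
             admittime=T("2102-01-01 00:00"),
             dischtime=T("2102-01-08 00:00"),
             admission_type="URGENT", ethnicity="ASIAN",
             hospital_expire_flag=0)])
    # hadm 10: ER -> ICU -> ward; hadm 11: ICU, ward(12h), ICU again
    db["transfers"] = pd.DataFrame([
        dict(row_id=1, subject_id=1, hadm_id=10, curr_careunit="MICU",
             curr_wardid=12, intime=T("2101-01-01 10:00"),
             outtime=T("2101-01-04 10:00"), eventtype="admit"),
        dict(row_id=2, subject_id=1, hadm_id=10, curr_careunit=None,
             curr_wardid=30, intime=T("2101-01-04 10:00"),
             outtime=T("2101-01-10 10:00"), eventtype="transfer"),
        dict(row_id=3, subject_id=1, hadm_id=11, curr_careunit="SICU",
             curr_wardid=12, intime=T("2101-03-01 08:00"),
             outtime=T("2101-03-02 08:00"), eventtype="admit"),
        dict(row_id=4, subject_id=1, hadm_id=11, curr_careunit=None,
             curr_wardid=31, intime=T("2101-03-02 08:00"),
             outtime=T("2101-03-02 20:00"), eventtype="transfer"),
        dict(row_id=5, subject_id=1, hadm_id=11, curr_careunit="SICU",
             curr_wardid=12, intime=T("2101-03-02 20:00"),
             outtime=T("2101-03-05 08:00"), eventtype="transfer")])
    # hadm 12 has no transfer rows at all
    db["services"] = pd.DataFrame([
        dict(row_id=1, subject_id=1, hadm_id=10,
             transfertime=T("2101-01-01 10:00"), curr_service="MED"),
        dict(row_id=2, subject_id=1, hadm_id=11,
             transfertime=T("2101-03-01 08:00"), curr_service="SURG"),
        dict(row_id=3, subject_id=2, hadm_id=12,
             transfertime=T("2102-01-01 00:00"), curr_service="MED")])
    return db


@pytest.fixture(scope="module")
def manual_result():
    return run_etl(_manual_source())


class TestVisitDetail:
    def test_er_icu_ward_sequence_gives_three_chained_rows(
            self, manual_result):
        vd = manual_result.cdm["visit_detail"]
        vo = manual_result.cdm["visit_occurrence"]
        visit = vo[vo["visit_source_value"].str.startswith("EMERGENCY")]
        chain = vd[vd["visit_occurrence_id"]
                   == visit["visit_occurrence_id"].iloc[0]] \
            .sort_values("visit_detail_start_datetime")
        assert len(chain) == 3
        # middle row is the ICU segment
        assert chain["visit_detail_concept_id"].iloc[1] == 32037
        # chained chronologically: each row knows its predecessor
        ids = chain["visit_detail_id"].tolist()
        assert chain["preceding_visit_detail_id"].tolist() \
            == [None, ids[0], ids[1]] \
            or pd.isna(chain["preceding_visit_detail_id"].iloc[0])

    def test_icu_return_within_24h_never_merged(self, manual_result):
        vd = manual_result.cdm["visit_detail"]
        icu = vd[vd["visit_detail_concept_id"] == 32037]
        # hadm 11 re-enters the ICU after a 12-hour ward interlude
        per_visit = icu.groupby("visit_occurrence_id").size()
        assert per_visit.max() == 2

    def test_admission_without_transfers_gets_synthetic_detail(
            self, manual_result):
        vd = manual_result.cdm["visit_detail"]
        vo = manual_result.cdm["visit_occurrence"]
        urgent = vo[vo["visit_source_value"].str.startswith("URGENT")]
        rows = vd[vd["visit_occurrence_id"]
                  == urgent["visit_occurrence_id"].iloc[0]]
        assert len(rows) == 1
        assert rows["visit_detail_start_datetime"].iloc[0] \
            == urgent["visit_start_datetime"].iloc[0]

    def test_details_contained_in_visit_interval(self, small_result):
        vd = small_result.cdm["visit_detail"]
        vo = small_result.cdm["visit_occurrence"].set_index(
            "visit_occurrence_id")
        j = vd.join(vo, on="visit_occurrence_id", rsuffix="_v")
        assert (j["visit_detail_start_datetime"]
                >= j["visit_start_datetime"]).all()
        assert (j["visit_detail_end_datetime"]
                <= j["visit_end_datetime"]).all()

    def test_chains_time_ordered(self, small_result):
        vd = small_result.cdm["visit_detail"]
        for _vid, grp in vd.groupby("visit_occurrence_id"):
            g = grp.sort_values("visit_detail_start_datetime")
            assert (g["visit_detail_end_datetime"].iloc[:-1].values
                    <= g["visit_detail_start_datetime"].iloc[1:].values).all()

    def test_overlapping_transfers_abort_with_admission_id(self):
        from mimic2omop.source import SourceIntegrityError
        db = _manual_source()
        db["transfers"].loc[1, "intime"] = T("2101-01-03 10:00")
        with pytest.raises((EtlIntegrityError, SourceIntegrityError),
                           match="10"):
            run_etl(db)


class TestMeasurement:
    def test_union_of_four_sources(self, small_source, small_result):
        staged = small_result.cdm["measurement"]
        src = small_result.provenance
        by_table = src[src["cdm_table"] == "measurement"] \
            .groupby("source_table")["cdm_row_id"].nunique()
        assert by_table.sum() == len(staged)
        assert set(by_table.index) == {"chartevents", "labevents",
                                       "outputevents", "microbiologyevents"}

    def test_culture_organism_rows_typed_2000000007(self, small_result):
        meas = small_result.cdm["measurement"]
        orgs = meas[meas["measurement_type_concept_id"] == 2000000007]
        assert len(orgs) > 0
        assert set(orgs["value_as_concept_id"].unique()) \
            <= {4149419, 4011683}

    def test_observation_domain_chart_items_land_in_observation(
            self, small_result):
        meas = small_result.cdm["measurement"]
        obs = small_result.cdm["observation"]
        assert not (meas["measurement_source_value"]
                    .str.contains("Tobacco", na=False)).any()
        tobacco = obs[obs["observation_source_value"]
                      .str.contains("Tobacco", na=False)]
        assert len(tobacco) > 0
        assert (tobacco["observation_concept_id"] == 4041306).all()

    def test_fahrenheit_temperatures_normalized_to_celsius(
            self, small_result):
        meas = small_result.cdm["measurement"]
        temps = meas[meas["measurement_concept_id"] == 3020891]
        assert len(temps) > 0
        assert temps["value_as_number"].max() < 45.0
        assert (temps["unit_source_value"] == "Deg. C").all()

    def test_textual_lab_values_parsed(self, small_result):
        meas = small_result.cdm["measurement"]
        psa = meas[meas["value_source_value"] == "<0.5 ng/mL"]
        if len(psa):  # present in most seeds
            assert (psa["operator_concept_id"] == 4171756).all()
            assert (psa["value_as_number"] == 0.5).all()

    def test_storetime_not_carried(self, small_result):
        assert "storetime" not in small_result.cdm["measurement"].columns


class TestSpecimen:
    def test_one_specimen_per_lab_measurement(self, small_source,
                                              small_result):
        prov = small_result.provenance
        lab_meas = prov[(prov["cdm_table"] == "measurement")
                        & (prov["source_table"] == "labevents")]
        lab_spec = prov[(prov["cdm_table"] == "specimen")
                        & (prov["source_table"] == "labevents")]
        assert len(lab_spec) == len(lab_meas)

    def test_blood_culture_specimen_concept(self, small_result):
        spec = small_result.cdm["specimen"]
        blood = spec[spec["specimen_source_value"] == "Blood"]
        assert (blood["specimen_concept_id"] == 4048506).all()

    def test_specimens_link_to_existing_measurements(self, small_result):
        spec = small_result.cdm["specimen"]
        meas_ids = set(small_result.cdm["measurement"]["measurement_id"])
        assert set(spec["measurement_id"].dropna()) <= meas_ids


class TestDrugExposure:
    def test_ndc_with_mapping_resolves_to_rxnorm(self, small_result):
        de = small_result.cdm["drug_exposure"]
        vanco = de[de["drug_source_value"] == "Vancomycin"]
        assert len(vanco) > 0
        assert (vanco["drug_concept_id"] == 1838573).all()

    def test_unmappable_ndc_keeps_source_value_with_concept_zero(
            self, small_result):
        de = small_result.cdm["drug_exposure"]
        insulin = de[de["drug_source_value"] == "Insulin"]
        assert len(insulin) > 0
        assert (insulin["drug_concept_id"] == 0).all()

    def test_missing_end_imputed_as_start_and_reported(self, small_source,
                                                       small_result):
        n_missing = small_source["prescriptions"]["enddate"].isna().sum()
        assert small_result.report.flags.get("imputed_end", 0) == n_missing
        assert small_result.cdm["drug_exposure"][
            "drug_exposure_end_datetime"].notna().all()


class TestFactRelationships:
    def test_organism_with_three_tests_gives_six_reciprocal_rows(self):
        db = _manual_source()
        base = dict(subject_id=1, hadm_id=10, chartdate=T("2101-01-02"),
                    charttime=T("2101-01-02 09:00"), spec_itemid=70012,
                    spec_type_desc="BLOOD CULTURE", org_itemid=80002,
                    org_name="STAPH AUREUS COAG +", isolate_num=1)
        rows = [dict(base, row_id=1)]
        for i, (ab, name) in enumerate(
                [(90004, "GENTAMICIN"), (90012, "VANCOMYCIN"),
                 (90016, "OXACILLIN")]):
            rows.append(dict(base, row_id=2 + i, ab_itemid=ab, ab_name=name,
                             dilution_comparison="<=", dilution_value=0.5,
                             dilution_text="<=0.5", interpretation="S"))
        db["microbiologyevents"] = pd.DataFrame(rows)
        res = run_etl(db)
        fr = res.cdm["fact_relationship"]
        micro = fr[fr["relationship_concept_id"].isin([2000000016,
                                                       2000000017])]
        assert len(micro) == 6
        # reciprocal pairing: both directions present
        fwd = micro[micro["relationship_concept_id"] == 2000000016]
        rev = micro[micro["relationship_concept_id"] == 2000000017]
        assert set(zip(fwd["fact_id_1"], fwd["fact_id_2"])) \
            == set(zip(rev["fact_id_2"], rev["fact_id_1"]))

    def test_no_microbiology_no_organism_relationships(self):
        res = run_etl(_manual_source())
        fr = res.cdm["fact_relationship"]
        assert not fr["relationship_concept_id"].isin(
            [2000000016, 2000000017]).any()

    def test_box_query_returns_exactly_the_organisms_panel(self):
        from mimic2omop import antibiogram_by_fact_relationship
        db = _manual_source()
        base = dict(subject_id=1, hadm_id=10, chartdate=T("2101-01-02"),
                    charttime=T("2101-01-02 09:00"), spec_itemid=70012,
                    spec_type_desc="BLOOD CULTURE", org_itemid=80002,
                    org_name="STAPH AUREUS COAG +", isolate_num=1)
        rows = [dict(base, row_id=1),
                dict(base, row_id=2, ab_itemid=90012, ab_name="VANCOMYCIN",
                     interpretation="S"),
                dict(base, row_id=3, ab_itemid=90004, ab_name="GENTAMICIN",
                     interpretation="R"),
                # a second, different organism with its own panel
                dict(base, row_id=4, org_itemid=80155,
                     org_name="ESCHERICHIA COLI"),
                dict(base, row_id=5, org_itemid=80155,
                     org_name="ESCHERICHIA COLI", ab_itemid=90008,
                     ab_name="CEFTRIAXONE", interpretation="S")]
        db["microbiologyevents"] = pd.DataFrame(rows)
        res = run_etl(db)
        panel = antibiogram_by_fact_relationship(res.cdm, 4149419, 46235217)
        assert panel == {"VANCOMYCIN", "GENTAMICIN"}


class TestRunEtl:
    def test_rerun_is_identical(self, small_source, small_result):
        again = run_etl(small_source)
        assert small_result.cdm.equals(again.cdm)

    def test_conservation_closes_for_every_source_table(self, small_result):
        rep = small_result.report
        for table, inp in rep.input_rows.items():
            assert inp == rep.linked_rows[table] \
                + rep.dropped_total(table), table

    def test_every_emitted_row_has_provenance(self, small_result):
        prov = small_result.provenance
        for table in ("person", "visit_occurrence", "visit_detail",
                      "measurement", "drug_exposure",
                      "condition_occurrence", "note"):
            pk = CDM_PRIMARY_KEYS[table]
            emitted = set(small_result.cdm[table][pk])
            linked = set(prov.loc[prov["cdm_table"] == table, "cdm_row_id"])
            assert emitted <= linked, table


@pytest.mark.parametrize("table", sorted(CDM_TABLES))
def test_target_table_loaded_correctly(table, small_result):
    """Per-target-table unit check: key uniqueness and required non-nulls."""
    df = small_result.cdm[table]
    pk = CDM_PRIMARY_KEYS[table]
    if pk is not None:
        assert df[pk].notna().all(), f"{table}.{pk} has nulls"
        assert not df[pk].duplicated().any(), f"{table}.{pk} duplicated"
    for col in df.columns:
        if col.endswith("_concept_id") and table not in (
                "concept", "concept_relationship"):
            assert df[col].notna().all(), f"{table}.{col} has nulls"
    assert small_result.report.target_rows[table] == len(df)


def test_integrity_violations_empty_on_generated_cohorts(small_result):
    assert small_result.cdm.integrity_violations() == []
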
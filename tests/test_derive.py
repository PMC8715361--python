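"""Clinical derivations: value parsing, unit conversion, scores, tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mimic2omop import (Saps2Input, build_denormalized,
                        build_icustays_table, build_microbiology_table,
                        calculated_osmolarity, corrected_calcium,
                        corrected_potassium, normalize_temperature,
                        parse_lab_value, pf_ratio, saps2, saps2_mortality)
from mimic2omop.derive import UnitError, band_points


class TestParseLabValue:
    @pytest.mark.parametrize("text,op,num,unit,residual", [
        ("<0.5 ng/mL", "<", 0.5, "ng/mL", ""),
        ("7.35", "=", 7.35, None, ""),
        ("NEGATIVE", "=", None, None, "NEGATIVE"),
        (">=16", "≥", 16.0, None, ""),
        ("<= 4 mmol/L", "≤", 4.0, "mmol/L", ""),
        ("  120  mg/dL ", "=", 120.0, "mg/dL", ""),
        ("", "=", None, None, ""),
        (None, "=", None, None, ""),
        ("TR @ 1:8", "=", None, None, "TR @ 1:8"),
    ])
    def test_grammar_cases(self, text, op, num, unit, residual):
        p = parse_lab_value(text)
        assert (p.operator, p.number, p.unit, p.residual) \
            == (op, num, unit, residual)

    def test_total_and_lossless_on_fuzzed_strings(self):
        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(st.text(st.characters(codec="ascii",
                                     exclude_categories=("Cc",)),
                       max_size=25))
        def check(text):
            p = parse_lab_value(text)
            if p.number is None:
                assert p.residual == " ".join(text.split())
            else:
                # numeric parses reassemble the normalized input
                want = " ".join(text.replace("<=", "≤").replace(">=", "≥")
                                .replace("=<", "≤").replace("=>", "≥")
                                .split())
                got = p.reconstruct()
                assert _normalize_numeric(got).replace(" ", "") \
                    == _normalize_numeric(want).replace(" ", "")
        check()


def _normalize_numeric(s: str) -> str:
    out = []
    spaced = (s.replace("<", " < ").replace(">", " > ")
              .replace("≤", " ≤ ").replace("≥", " ≥ ").replace("=", " "))
    for token in spaced.split():
        try:
            out.append(f"{float(token):g}")
        except ValueError:
            out.append(token)
    return " ".join(out)


class TestTemperature:
    @pytest.mark.parametrize("value,unit,expected", [
        (37.0, "C", 37.0), (98.6, "F", 37.0), (212.0, "F", 100.0),
        (95.0, "Deg. F", 35.0), (36.6, "Deg. C", 36.6),
    ])
    def test_conversions(self, value, unit, expected):
        assert normalize_temperature(value, unit) == expected

    def test_unknown_unit_raises(self):
        with pytest.raises(UnitError):
            normalize_temperature(37.0, "K")

    def test_roundtrip_within_tenth_of_degree(self):
        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(st.floats(30.0, 43.0))
        def check(c):
            f = c * 9.0 / 5.0 + 32.0
            assert abs(normalize_temperature(f, "F") - c) <= 0.1
        check()


def test_derived_formulas_match_committed_oracle(derived_oracle):
    fns = {"corrected_calcium": lambda r: corrected_calcium(
               float(r.input_1), float(r.input_2)),
           "corrected_potassium": lambda r: corrected_potassium(
               float(r.input_1), float(r.input_2)),
           "pf_ratio": lambda r: pf_ratio(float(r.input_1),
                                          float(r.input_2)),
           "calculated_osmolarity": lambda r: calculated_osmolarity(
               float(r.input_1), float(r.input_2), float(r.input_3)),
           "normalize_temperature": lambda r: normalize_temperature(
               float(r.input_1), r.input_2)}
    for row in derived_oracle.itertuples(index=False):
        got = fns[row.quantity](row)
        assert got == pytest.approx(float(row.expected), abs=1e-9), row


@pytest.mark.parametrize("fn,args", [
    (corrected_calcium, (0.0, 4.0)),
    (corrected_calcium, (9.0, -1.0)),
    (corrected_potassium, (4.0, 6.0)),
    (corrected_potassium, (4.0, 8.5)),
    (pf_ratio, (100.0, 0.0)),
    (calculated_osmolarity, (-1.0, 0.0, 0.0)),
])
def test_derived_formula_validation_errors(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


class TestSaps2:
    def test_zero_band_young_scheduled_surgical_scores_zero(self):
        res = saps2(Saps2Input(
            age=30, heart_rate=80, systolic_bp=120, temperature=37,
            urine_output=1.5, bun=20, wbc=8, potassium=4, sodium=138,
            bicarbonate=24, bilirubin=0.5, gcs=15, chronic="none",
            admission="scheduled_surgical"))
        assert res.score == 0

    def test_hand_scored_oracle_table(self, saps2_oracle):
        for row in saps2_oracle.itertuples(index=False):
            inp = Saps2Input(
                age=row.age,
                heart_rate=_opt(row.heart_rate),
                systolic_bp=_opt(row.systolic_bp),
                temperature=_opt(row.temperature),
                ventilated=bool(row.ventilated),
                pf_ratio=_opt(row.pf_ratio),
                urine_output=_opt(row.urine_output),
                bun=_opt(row.bun), wbc=_opt(row.wbc),
                potassium=_opt(row.potassium), sodium=_opt(row.sodium),
                bicarbonate=_opt(row.bicarbonate),
                bilirubin=_opt(row.bilirubin), gcs=_opt(row.gcs),
                chronic=row.chronic, admission=row.admission)
            res = saps2(inp)
            assert res.score == row.expected_score, f"patient {row.patient}"

    def test_missing_components_score_zero_and_are_reported(self):
        res = saps2(Saps2Input(age=30, admission="scheduled_surgical"))
        assert res.score == 0
        assert "heart_rate" in res.missing

    def test_mortality_strictly_increasing_and_small_at_zero(self):
        probs = [saps2_mortality(s) for s in range(0, 160)]
        assert all(b > a for a, b in zip(probs, probs[1:]))
        assert probs[0] < 0.001

    def test_invalid_glasgow_rejected(self):
        with pytest.raises(ValueError, match="Glasgow"):
            saps2(Saps2Input(age=30, gcs=2))

    def test_band_edges_half_open(self):
        assert band_points("sodium", 144.99) == 0
        assert band_points("sodium", 145.0) == 1
        assert band_points("gcs", 13.0) == 5
        assert band_points("gcs", 14.0) == 0


def _opt(v):
    return None if pd.isna(v) else float(v)


class TestDenormalized:
    def test_row_counts_and_original_columns_preserved(self, small_result):
        den, warnings = build_denormalized(small_result.cdm, None)
        assert warnings == []
        meas = small_result.cdm["measurement"]
        dmeas = den["measurement"]
        assert len(dmeas) == len(meas)
        for col in meas.columns:
            assert (dmeas[col].fillna(-1) == meas[col].fillna(-1)).all() \
                or meas[col].isna().equals(dmeas[col].isna()), col

    def test_culture_organism_type_gets_its_name(self, small_result):
        den, _ = build_denormalized(small_result.cdm, None)
        dmeas = den["measurement"]
        orgs = dmeas[dmeas["measurement_type_concept_id"] == 2000000007]
        assert (orgs["measurement_type_concept_name"]
                == "Labs - Culture Organisms").all()

    def test_dangling_concept_named_unknown(self, small_result):
        import copy
        cdm = copy.deepcopy(small_result.cdm)
        cdm.tables["measurement"].loc[0, "measurement_concept_id"] = 987654
        den, warnings = build_denormalized(cdm, None)
        assert any("dangling" in w for w in warnings)
        assert den["measurement"]["measurement_concept_name"].iloc[0] \
            == "Unknown (987654)"


class TestMicrobiologyTable:
    def test_pairs_flattened_one_row_each(self, small_result):
        micro = build_microbiology_table(small_result.cdm)
        fr = small_result.cdm["fact_relationship"]
        n_pairs = (fr["relationship_concept_id"] == 2000000016).sum()
        with_ab = micro["antibiotic_measurement_id"].notna().sum()
        assert with_ab == n_pairs

    def test_organism_without_tests_kept_with_absent_antibiotic(self):
        from mimic2omop import run_etl
        from tests.test_etl import _manual_source
        db = _manual_source()
        db["microbiologyevents"] = pd.DataFrame([dict(
            row_id=1, subject_id=1, hadm_id=10,
            chartdate=pd.Timestamp("2101-01-02"),
            charttime=pd.Timestamp("2101-01-02 09:00"), spec_itemid=70012,
            spec_type_desc="BLOOD CULTURE", org_itemid=80002,
            org_name="STAPH AUREUS COAG +", isolate_num=1)])
        res = run_etl(db)
        micro = build_microbiology_table(res.cdm)
        assert len(micro) == 1
        assert pd.isna(micro["antibiotic_source_value"].iloc[0])

    def test_both_query_routes_agree(self, small_result):
        from mimic2omop import (antibiogram_by_denormalized,
                                antibiogram_by_fact_relationship)
        micro = build_microbiology_table(small_result.cdm)
        for org in (4149419, 4011683):
            for spec in (46235217, 3018190):
                assert antibiogram_by_fact_relationship(
                    small_result.cdm, org, spec) \
                    == antibiogram_by_denormalized(micro, org, spec)


class TestIcustaysTable:
    def test_one_row_per_icu_segment(self, manual_result_shared):
        icu = build_icustays_table(manual_result_shared.cdm)
        # hadm 11 has two ICU segments, hadm 10 one, hadm 12 none
        assert len(icu) == 3
        per_visit = icu.groupby("visit_occurrence_id").size()
        assert sorted(per_visit) == [1, 2]

    def test_36_hour_segment_is_one_and_a_half_days(self,
                                                    manual_result_shared):
        icu = build_icustays_table(manual_result_shared.cdm)
        # hadm 10 ICU: Jan 1 10:00 -> Jan 4 10:00 = 3 days exactly
        assert 3.0 in set(icu["los_days"])
        # hadm 11 first ICU segment: 24 h
        assert 1.0 in set(icu["los_days"])

    def test_no_icu_segments_empty_table(self):
        from mimic2omop import SourceDatabase, run_etl
        res = run_etl(SourceDatabase())
        assert len(build_icustays_table(res.cdm)) == 0


@pytest.fixture(scope="module")
def manual_result_shared():
    from mimic2omop import run_etl
    from tests.test_etl import _manual_source
    return run_etl(_manual_source())
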
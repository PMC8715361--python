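"""Vocabulary store: id bands, alignment cases, routing, similarity."""

import pytest
from hypothesis import given, settings, strategies as st

from mimic2omop import VocabularyStore, label_similarity, rank_candidates
from mimic2omop.vocabulary import (Concept, EXTENSION_BAND, LOCAL_BAND_START,
                                   LOCAL_VOCABULARY, VocabularyFormatError,
                                   VocabularyIntegrityError,
                                   VocabularyLookupError)


def _write_athena(tmp_path, concept_rows, rel_rows=()):
    c = tmp_path / "CONCEPT.tsv"
    header = ("concept_id\tconcept_name\tdomain_id\tvocabulary_id\t"
              "concept_class_id\tstandard_concept\tconcept_code\t"
              "valid_start_date\tvalid_end_date\tinvalid_reason\n")
    c.write_text(header + "".join(
        f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\tClass\t{r[4]}\t{r[5]}\t"
        "19700101\t20991231\t\n" for r in concept_rows))
    r = tmp_path / "CONCEPT_RELATIONSHIP.tsv"
    rheader = ("concept_id_1\tconcept_id_2\trelationship_id\t"
               "valid_start_date\tvalid_end_date\tinvalid_reason\n")
    r.write_text(rheader + "".join(
        f"{a}\t{b}\t{rel}\t19700101\t20991231\t\n" for a, b, rel in rel_rows))
    return c, r


class TestLoading:
    def test_empty_files_with_headers_load_empty_store(self, tmp_path):
        c, r = _write_athena(tmp_path, [])
        store = VocabularyStore.load_athena_vocabulary(c, r)
        assert store.concept_frame().empty

    def test_lookup_by_vocabulary_and_code(self, tmp_path):
        c, r = _write_athena(
            tmp_path,
            [(1, "Sodium lab", "Measurement", "LOINC", "S", "2951-2"),
             (2, "HTN icd", "Condition", "ICD9CM", "", "4019"),
             (3, "HTN snomed", "Condition", "SNOMED", "S", "59621000")],
            [(2, 3, "Maps to")])
        store = VocabularyStore.load_athena_vocabulary(c, r)
        assert store.by_code("LOINC", "2951-2").concept_id == 1
        assert store.maps_to("4019", "ICD9CM") == [3]

    def test_missing_columns_rejected(self, tmp_path):
        _c, r = _write_athena(tmp_path, [])
        bad = tmp_path / "CONCEPT_BAD.tsv"
        bad.write_text("concept_id\tconcept_name\n1\tx\n")
        with pytest.raises(VocabularyFormatError, match="domain_id"):
            VocabularyStore.load_athena_vocabulary(bad, r)

    def test_duplicate_concept_id_rejected(self, tmp_path):
        c, r = _write_athena(
            tmp_path, [(1, "a", "Measurement", "LOINC", "S", "1-1"),
                       (1, "b", "Measurement", "LOINC", "S", "1-2")])
        with pytest.raises(VocabularyIntegrityError, match="duplicate"):
            VocabularyStore.load_athena_vocabulary(c, r)

    def test_fixture_manifest_counts(self, vocab):
        frame = vocab.concept_frame()
        # hand-counted from the committed fixture file
        assert len(frame) == 115
        by_domain = frame["domain_id"].value_counts()
        assert by_domain["Measurement"] == 33
        assert by_domain["Condition"] == 15
        assert by_domain["Drug"] == 11


class TestBands:
    def test_local_ids_sequential_from_band_start(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        ids = [store.register_local_concept(f"Item {i}", "Measurement",
                                            "d_items", code=str(i)).concept_id
               for i in range(50)]
        assert ids == list(range(LOCAL_BAND_START, LOCAL_BAND_START + 50))
        assert all(store.get(i).vocabulary_id == LOCAL_VOCABULARY
                   for i in ids)

    def test_same_label_twice_gets_distinct_ids(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        a = store.register_local_concept("Temperature F", "Measurement",
                                         "d_items")
        b = store.register_local_concept("Temperature F", "Measurement",
                                         "d_items")
        assert a.concept_id != b.concept_id

    def test_culture_extension_ids_are_stable(self, vocab):
        assert vocab.extension_id("Labs - Culture Organisms") == 2000000007
        assert vocab.extension_id("Labs - Culture Sensitivity") == 2000000008
        assert vocab.extension_id("Labs - Culture Organisms") == 2000000007

    def test_unknown_extension_name_gets_fresh_band_id(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        c = store.register_extension_concept("Completely New Type",
                                             "Type Concept")
        assert EXTENSION_BAND[0] <= c.concept_id < EXTENSION_BAND[1]
        assert store.register_extension_concept(
            "Completely New Type").concept_id == c.concept_id

    def test_band_partition_property(self, vocab):
        @settings(max_examples=20, deadline=None, derandomize=True)
        @given(st.lists(st.sampled_from(["local", "extension"]),
                        max_size=10))
        def check(kinds):
            import copy
            store = copy.deepcopy(vocab)
            for i, kind in enumerate(kinds):
                if kind == "local":
                    store.register_local_concept(f"L{i}", "Measurement",
                                                 "d_items")
                else:
                    store.register_extension_concept(f"E{i}")
            frame = store.concept_frame()
            std = frame["concept_id"] < EXTENSION_BAND[0]
            ext = (frame["concept_id"] >= EXTENSION_BAND[0]) \
                & (frame["concept_id"] < EXTENSION_BAND[1])
            loc = frame["concept_id"] >= LOCAL_BAND_START
            assert (std.astype(int) + ext.astype(int)
                    + loc.astype(int)).eq(1).all()
        check()


class TestMapsTo:
    def test_absent_code_returns_empty(self, vocab):
        assert vocab.maps_to("0000", "ICD9CM") == []

    def test_single_target(self, vocab):
        assert vocab.maps_to("4019", "ICD9CM") == [320128]

    def test_one_to_many_sorted_ascending(self, vocab):
        assert vocab.maps_to("0389", "ICD9CM") == [132797, 434821]

    def test_unknown_vocabulary_raises(self, vocab):
        with pytest.raises(VocabularyLookupError):
            vocab.maps_to("x", "NO-SUCH-VOCAB")


class TestRanking:
    def test_identical_label_scores_one(self):
        cands = [Concept(1, "Body temperature", "Measurement", "LOINC"),
                 Concept(2, "Body weight", "Measurement", "LOINC")]
        ranked = rank_candidates("Body temperature", cands, k=2)
        assert ranked[0][0].concept_id == 1
        assert ranked[0][1] == 1.0

    def test_partial_overlap_hand_computed(self):
        # tokens('temperature f') = {temperature, f};
        # tokens('Body temperature') = {body, temperature}
        # |intersection| / sqrt(2*2) = 1/2; no bonus (strings differ)
        assert label_similarity("temperature f", "Body temperature") == 0.5
        assert label_similarity("temperature f", "Body weight") == 0.0
        cands = [Concept(1, "Body temperature", "Measurement", "LOINC"),
                 Concept(2, "Body weight", "Measurement", "LOINC")]
        assert rank_candidates("temperature f", cands, 1)[0][0] \
            .concept_id == 1

    def test_disjoint_tokens_score_zero(self):
        cands = [Concept(1, "Heart rate", "Measurement", "LOINC")]
        assert rank_candidates("platelet count", cands, 1)[0][1] == 0.0

    def test_score_bounds_property(self):
        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.text("abc XYZ", min_size=1, max_size=30),
               st.text("abc XYZ", min_size=1, max_size=30))
        def check(a, b):
            s = label_similarity(a, b)
            assert 0.0 <= s <= 1.0
            if a.strip():
                assert label_similarity(a, a) in (0.0, 1.0)
        check()

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates("  ", [], k=1)

    def test_ties_broken_by_ascending_id(self):
        cands = [Concept(9, "Rate heart", "Measurement", "LOINC"),
                 Concept(2, "Heart rate", "Measurement", "LOINC")]
        ranked = rank_candidates("cardiac", cands, k=2)
        assert [c.concept_id for c, _ in ranked] == [2, 9]


class TestAlignment:
    def test_standard_loinc_code_is_already_standard(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept(
            "Sodium", "Measurement", "d_labitems", code="2951-2",
            code_vocabulary="LOINC")
        d = store.align_concept(local)
        assert (d.case_tag, d.standard_concept_id) \
            == ("already_standard", 3019550)

    def test_relationship_case_uses_lowest_target(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept(
            "Septicemia NOS", "Condition", "d_icd_diagnoses", code="0389",
            code_vocabulary="ICD9CM")
        d = store.align_concept(local)
        assert d.case_tag == "via_relationship"
        assert d.standard_concept_id == 132797
        assert d.all_targets == (132797, 434821)

    def test_manual_table_case(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("Temperature F", "Measurement",
                                             "d_items", code="678")
        d = store.align_concept(local)
        assert (d.case_tag, d.standard_concept_id) == ("manual", 3020891)

    def test_no_evidence_yields_unmapped_zero(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("zzqx", "Condition", "d_items",
                                             code="999999")
        d = store.align_concept(local)
        assert (d.case_tag, d.standard_concept_id) == ("unmapped", 0)

    def test_suggestion_keeps_standard_id_zero(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("PH (Arterial)", "Measurement",
                                             "d_items", code="223830")
        d = store.align_concept(local)
        assert d.case_tag == "suggested"
        assert d.standard_concept_id == 0
        assert d.score > 0
        assert "3014605" in d.comment

    def test_alignment_is_deterministic(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("Temperature F", "Measurement",
                                             "d_items", code="678")
        assert store.align_concept(local) == store.align_concept(local)


class TestDomainRouting:
    def test_measurement_domain_routes_to_measurement(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept(
            "Sodium", "Measurement", "d_labitems", code="2951-2",
            code_vocabulary="LOINC")
        d = store.align_concept(local)
        assert store.domain_route(d, "MEASUREMENT") == "MEASUREMENT"

    def test_observation_domain_overrides_source_table(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("Tobacco Use", "Observation",
                                             "d_items", code="920")
        d = store.align_concept(local)
        assert store.domain_route(d, "MEASUREMENT") == "OBSERVATION"

    def test_unmapped_falls_back_to_source_default(self, vocab):
        import copy
        store = copy.deepcopy(vocab)
        local = store.register_local_concept("zzqx", "Condition", "d_items",
                                             code="999999")
        d = store.align_concept(local)
        assert store.domain_route(d, "MEASUREMENT") == "MEASUREMENT"

    def test_nonroutable_domain_raises_naming_domain(self, vocab):
        import copy
        from mimic2omop.vocabulary import MappingDecision
        store = copy.deepcopy(vocab)
        d = MappingDecision(LOCAL_BAND_START, 4149419, "manual", 1.0, "")
        with pytest.raises(VocabularyLookupError, match="Meas Value"):
            store.domain_route(d, "MEASUREMENT")

    def test_route_never_returns_vocabulary_table(self, vocab):
        from mimic2omop.vocabulary import DOMAIN_TABLE
        assert "CONCEPT" not in DOMAIN_TABLE.values()
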
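"""Stage orchestration: synth | vocab | etl | derive | nlp | qa.

Stages run in dependency order inside one call; when a requested stage needs
the output of a stage that was not requested, the artifact is loaded from
the output directory (so partial runs compose), and a missing artifact
raises :class:`DependencyError` naming the stage that would produce it.

The derive stage appends derived measurements (corrected calcium and
potassium, calculated osmolarity, PaO2/FiO2) and per-ICU-stay severity
scores to the CDM, continuing the global id sequence, and materializes the
denormalized and specialized analyst tables.  The nlp stage populates
NOTE_NLP from the numeric-entity extractor and the section segmenter and
routes extracted values into MEASUREMENT.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, STAGES, STAGE_DEPENDENCIES
from .derive import (Saps2Input, saps2, corrected_calcium,
                     corrected_potassium, pf_ratio, calculated_osmolarity,
                     band_points, build_denormalized,
                     build_microbiology_table, build_icustays_table,
                     ICU_VISIT_DETAIL_CONCEPT)
from .etl import (CdmDatabase, EtlResult, GlobalSequence, TransformReport,
                  run_etl)
from .notes import (extract_numeric_entities, harvest_section_templates,
                    segment_note, ENTITY_CONCEPTS, NLP_SYSTEM)
from .quality import evaluate
from .schemas import CDM_TABLES, coerce_table
from .source import SourceDatabase
from .synthetic import generate_source
from .vocabulary import VocabularyStore

log = logging.getLogger("mimic2omop")


class DependencyError(RuntimeError):
    """A requested stage's dependency output is unavailable."""


# measurement concepts consumed by the severity score
_SAPS_CONCEPTS = {
    3027018: "heart_rate", 3004249: "systolic_bp", 3020891: "temperature",
    3032652: "gcs", 3023103: "potassium", 3019550: "sodium",
    3016293: "bicarbonate", 3024128: "bilirubin", 3010813: "wbc",
    3013682: "bun", 3013290: "pao2", 3020716: "fio2", 3014315: "urine",
}
_VENT_PROCEDURES = {4202832, 4230167}  # intubation, ventilation management

#: inputs of the per-admission derived values
_DERIVED_INPUTS = {
    "calcium": 3006906, "albumin": 3024561, "sodium": 3019550,
    "glucose": 3004501, "bun": 3013682, "potassium": 3023103,
    "ph": 3014605, "pao2": 3013290, "fio2": 3020716,
}


def _worst_points(component: str, values) -> float | None:
    """Value with the highest point contribution (the 'worst' value)."""
    vals = [v for v in values if v is not None and not np.isnan(v)]
    if not vals:
        return None
    if component == "gcs":
        vals = [min(max(v, 3.0), 15.0) for v in vals]
    return max(vals, key=lambda v: band_points(component, v))


def compute_saps2_per_stay(cdm: CdmDatabase) -> pd.DataFrame:
    """SAPS II over the worst values of the first 24 ICU hours per stay."""
    vd = cdm.tables["visit_detail"]
    icu = vd[vd["visit_detail_concept_id"] == ICU_VISIT_DETAIL_CONCEPT]
    if not len(icu):
        return pd.DataFrame()
    meas = cdm.tables["measurement"]
    meas = meas[meas["measurement_concept_id"].isin(_SAPS_CONCEPTS)]
    person = cdm.tables["person"].set_index("person_id")["birth_datetime"]
    visits = cdm.tables["visit_occurrence"].set_index("visit_occurrence_id")
    procs = cdm.tables["procedure_occurrence"]
    vent_visits = set(
        procs.loc[procs["procedure_concept_id"].isin(_VENT_PROCEDURES),
                  "visit_occurrence_id"].dropna())
    by_visit = dict(tuple(meas.groupby("visit_occurrence_id")))
    rows = []
    for stay in icu.itertuples(index=False):
        start = stay.visit_detail_start_datetime
        end = min(start + pd.Timedelta(hours=24),
                  stay.visit_detail_end_datetime)
        pool = by_visit.get(stay.visit_occurrence_id)
        values: dict[str, list[float]] = {}
        if pool is not None:
            window = pool[(pool["measurement_datetime"] >= start)
                          & (pool["measurement_datetime"] <= end)]
            for cid, grp in window.groupby("measurement_concept_id"):
                values[_SAPS_CONCEPTS[int(cid)]] = \
                    grp["value_as_number"].dropna().tolist()
        dob = person.loc[stay.person_id]
        age = (start.year - dob.year) + (start.dayofyear
                                         - dob.dayofyear) / 365.25
        src = str(visits.loc[stay.visit_occurrence_id,
                             "visit_source_value"] or "")
        parts = src.split("/")
        surgical = len(parts) > 1 and parts[1] in ("SURG", "CSURG", "NSURG")
        if surgical:
            admission = "scheduled_surgical" if parts[0] == "ELECTIVE" \
                else "unscheduled_surgical"
        else:
            admission = "medical"
        ventilated = stay.visit_occurrence_id in vent_visits
        pf = None
        if ventilated and values.get("pao2") and values.get("fio2"):
            pf = pf_ratio(min(values["pao2"]), max(values["fio2"]))
        urine = sum(values.get("urine", [])) / 1000.0 \
            if values.get("urine") else None
        inp = Saps2Input(
            age=min(age, 120.0),
            heart_rate=_worst_points("heart_rate",
                                     values.get("heart_rate", [])),
            systolic_bp=_worst_points("systolic_bp",
                                      values.get("systolic_bp", [])),
            temperature=_worst_points("temperature",
                                      values.get("temperature", [])),
            pf_ratio=pf, ventilated=ventilated, urine_output=urine,
            bun=_worst_points("bun", values.get("bun", [])),
            wbc=_worst_points("wbc", values.get("wbc", [])),
            potassium=_worst_points("potassium",
                                    values.get("potassium", [])),
            sodium=_worst_points("sodium", values.get("sodium", [])),
            bicarbonate=_worst_points("bicarbonate",
                                      values.get("bicarbonate", [])),
            bilirubin=_worst_points("bilirubin",
                                    values.get("bilirubin", [])),
            gcs=_worst_points("gcs", values.get("gcs", [])),
            admission=admission)
        res = saps2(inp)
        rows.append(dict(
            visit_detail_id=stay.visit_detail_id,
            person_id=stay.person_id,
            visit_occurrence_id=stay.visit_occurrence_id,
            window_start=start, window_end=end,
            saps2_score=res.score, predicted_mortality=round(res.mortality, 4),
            n_missing_components=len(res.missing)))
    return pd.DataFrame(rows)


def apply_derive_stage(result: EtlResult, vocab: VocabularyStore
                       ) -> dict[str, pd.DataFrame]:
    """Append derived rows to the CDM and build the analyst tables."""
    cdm = result.cdm
    seq = GlobalSequence(start=int(cdm.sequence_ids().max()) + 1
                         if len(cdm.sequence_ids()) else 0)
    derived_type = vocab.extension_id("Derived Value")
    score_attr = vocab.extension_id("Severity Score")
    concept_of = {"corrected_calcium": vocab.extension_id(
                      "Corrected Serum Calcium"),
                  "corrected_potassium": vocab.extension_id(
                      "Corrected Serum Potassium"),
                  "osmolarity": vocab.extension_id("Calculated Osmolarity"),
                  "pf_ratio": vocab.extension_id("PaO2 FiO2 Ratio")}

    meas = cdm.tables["measurement"]
    pool = meas[meas["measurement_concept_id"].isin(
        set(_DERIVED_INPUTS.values()))]
    latest = pool.sort_values("measurement_datetime").groupby(
        ["visit_occurrence_id", "measurement_concept_id"]).last()
    prov = result.provenance
    meas_prov = prov[prov["cdm_table"] == "measurement"].set_index(
        "cdm_row_id")
    new_rows = []
    new_prov = []

    def emit(visit_id, name, value, primary: pd.Series):
        mid = seq.allocate()
        new_rows.append(dict(
            measurement_id=mid, person_id=primary["person_id"],
            measurement_concept_id=concept_of[name],
            measurement_datetime=primary["measurement_datetime"],
            measurement_type_concept_id=derived_type,
            operator_concept_id=4172703, value_as_number=value,
            value_as_concept_id=0, unit_concept_id=0,
            unit_source_value=None, visit_occurrence_id=visit_id,
            visit_detail_id=None,
            measurement_source_value=f"{name} (derived)",
            measurement_source_concept_id=0, value_source_value=None))
        primary_id = int(primary["measurement_id"])
        if primary_id in meas_prov.index:
            src = meas_prov.loc[primary_id]
            if isinstance(src, pd.DataFrame):
                src = src.iloc[0]
            new_prov.append(dict(source_table=src["source_table"],
                                 source_row_id=src["source_row_id"],
                                 cdm_table="measurement", cdm_row_id=mid))

    for visit_id in latest.index.get_level_values(0).unique():
        sub = latest.loc[visit_id]
        have = {name: sub.loc[cid] for name, cid in _DERIVED_INPUTS.items()
                if cid in sub.index
                and pd.notna(sub.loc[cid, "value_as_number"])}
        if "calcium" in have and "albumin" in have:
            emit(visit_id, "corrected_calcium", corrected_calcium(
                have["calcium"]["value_as_number"],
                have["albumin"]["value_as_number"]), have["calcium"])
        if "potassium" in have and "ph" in have:
            ph = float(have["ph"]["value_as_number"])
            if 6.5 <= ph <= 8.0:
                emit(visit_id, "corrected_potassium", corrected_potassium(
                    have["potassium"]["value_as_number"], ph),
                    have["potassium"])
        if all(k in have for k in ("sodium", "glucose", "bun")):
            emit(visit_id, "osmolarity", calculated_osmolarity(
                have["sodium"]["value_as_number"],
                have["glucose"]["value_as_number"],
                have["bun"]["value_as_number"]), have["sodium"])
        if "pao2" in have and "fio2" in have:
            emit(visit_id, "pf_ratio", pf_ratio(
                have["pao2"]["value_as_number"],
                have["fio2"]["value_as_number"]), have["pao2"])

    if new_rows:
        add = coerce_table(pd.DataFrame(new_rows), CDM_TABLES["measurement"])
        cdm.tables["measurement"] = pd.concat(
            [cdm.tables["measurement"], add], ignore_index=True)
        result.provenance = pd.concat(
            [result.provenance, pd.DataFrame(new_prov)], ignore_index=True)

    saps = compute_saps2_per_stay(cdm)
    if len(saps):
        cohort = pd.DataFrame({
            "cohort_definition_id": score_attr,
            "subject_id": saps["person_id"],
            "cohort_start_date": saps["window_start"],
            "cohort_end_date": saps["window_end"],
            "attribute_definition_id": score_attr,
            "value_as_number": saps["saps2_score"].astype(float),
            "value_as_concept_id": 0})
        cdm.tables["cohort_attribute"] = pd.concat(
            [cdm.tables["cohort_attribute"],
             coerce_table(cohort, CDM_TABLES["cohort_attribute"])],
            ignore_index=True)

    result.report.target_rows["measurement"] = len(cdm.tables["measurement"])
    result.report.target_rows["cohort_attribute"] = \
        len(cdm.tables["cohort_attribute"])
    denorm, warnings = build_denormalized(cdm, vocab)
    for w in warnings:
        result.report.note(f"denormalization: {w}")
    tables = {f"{name}_denorm": df for name, df in denorm.items()}
    tables["microbiology"] = build_microbiology_table(cdm)
    tables["icustays"] = build_icustays_table(cdm)
    tables["saps2"] = saps
    return tables


def apply_nlp_stage(result: EtlResult, vocab: VocabularyStore
                    ) -> pd.DataFrame:
    """Populate NOTE_NLP and route extracted numeric values onward."""
    cdm = result.cdm
    notes = cdm.tables["note"]
    seq = GlobalSequence(start=int(cdm.sequence_ids().max()) + 1
                         if len(cdm.sequence_ids()) else 0)
    note_type = vocab.extension_id("Note-derived Value")
    nlp_rows = []
    meas_rows = []
    new_prov = []
    prov = result.provenance
    note_prov = prov[prov["cdm_table"] == "note"].set_index("cdm_row_id")
    texts = notes["note_text"].fillna("").tolist()
    templates = harvest_section_templates(texts) if texts else []

    for row in notes.itertuples(index=False):
        text = row.note_text or ""
        src = note_prov.loc[int(row.note_id)] \
            if int(row.note_id) in note_prov.index else None
        if isinstance(src, pd.DataFrame):
            src = src.iloc[0]

        def link(cdm_table, cdm_id):
            if src is not None:
                new_prov.append(dict(source_table=src["source_table"],
                                     source_row_id=src["source_row_id"],
                                     cdm_table=cdm_table, cdm_row_id=cdm_id))

        for ent in extract_numeric_entities(text):
            nid = seq.allocate()
            nlp_rows.append(dict(
                note_nlp_id=nid, note_id=row.note_id,
                section_concept_id=0, section_source_value=None,
                snippet=ent.snippet, offset_begin=ent.offset_begin,
                offset_end=ent.offset_end,
                lexical_variant=ent.lexical_variant,
                note_nlp_concept_id=ENTITY_CONCEPTS[ent.entity],
                note_nlp_source_concept_id=0, nlp_system=NLP_SYSTEM,
                nlp_datetime=row.note_datetime, term_exists="Y",
                value_as_number=ent.value, unit_source_value=ent.unit))
            link("note_nlp", nid)
            mid = seq.allocate()
            meas_rows.append(dict(
                measurement_id=mid, person_id=row.person_id,
                measurement_concept_id=ENTITY_CONCEPTS[ent.entity],
                measurement_datetime=row.note_datetime,
                measurement_type_concept_id=note_type,
                operator_concept_id=4172703, value_as_number=ent.value,
                value_as_concept_id=0,
                unit_concept_id=0, unit_source_value=ent.unit,
                visit_occurrence_id=row.visit_occurrence_id,
                visit_detail_id=None,
                measurement_source_value=f"note:{ent.entity}",
                measurement_source_concept_id=0,
                value_source_value=ent.lexical_variant))
            link("measurement", mid)
        for span in segment_note(text, templates):
            nid = seq.allocate()
            nlp_rows.append(dict(
                note_nlp_id=nid, note_id=row.note_id,
                section_concept_id=0, section_source_value=span.label,
                snippet=span.snippet, offset_begin=span.offset_begin,
                offset_end=span.offset_end, lexical_variant=span.label,
                note_nlp_concept_id=0, note_nlp_source_concept_id=0,
                nlp_system=NLP_SYSTEM, nlp_datetime=row.note_datetime,
                term_exists="Y", value_as_number=None,
                unit_source_value=None))
            link("note_nlp", nid)

    if nlp_rows:
        cdm.tables["note_nlp"] = pd.concat(
            [cdm.tables["note_nlp"],
             coerce_table(pd.DataFrame(nlp_rows), CDM_TABLES["note_nlp"])],
            ignore_index=True)
    if meas_rows:
        cdm.tables["measurement"] = pd.concat(
            [cdm.tables["measurement"],
             coerce_table(pd.DataFrame(meas_rows),
                          CDM_TABLES["measurement"])], ignore_index=True)
    if new_prov:
        result.provenance = pd.concat(
            [result.provenance, pd.DataFrame(new_prov)], ignore_index=True)
    result.report.target_rows["note_nlp"] = len(cdm.tables["note_nlp"])
    result.report.target_rows["measurement"] = len(cdm.tables["measurement"])
    return pd.DataFrame([t.__dict__ for t in templates])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineState:
    source: SourceDatabase | None = None
    vocab: VocabularyStore | None = None
    result: EtlResult | None = None


def _ordered_stages(requested) -> list[str]:
    req = set(requested)
    return [s for s in STAGES if s in req]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    state = PipelineState()
    manifest: dict = {"stages": {}, "config":
                      {"generator": config.generator.to_dict(),
                       "stages": list(config.stages)}}
    requested = _ordered_stages(config.stages)

    def need_source():
        if state.source is None:
            src_dir = out / "source"
            if not (src_dir / "PATIENTS.csv").exists():
                raise DependencyError(
                    "stage requires the source bundle; run the 'synth' "
                    "stage first")
            state.source = SourceDatabase.read_csv(src_dir)

    def need_vocab():
        if state.vocab is None:
            if config.concept_file and config.relationship_file:
                state.vocab = VocabularyStore.load_athena_vocabulary(
                    config.concept_file, config.relationship_file)
            else:
                state.vocab = VocabularyStore.fixture()

    def need_result():
        if state.result is None:
            cdm_dir = out / "cdm"
            rep = out / "report" / "transform_report.json"
            if not (cdm_dir / "PERSON.csv").exists() or not rep.exists():
                raise DependencyError(
                    "stage requires a transformed CDM; run the 'etl' stage "
                    "first")
            report = TransformReport(**json.loads(rep.read_text()))
            provenance = pd.read_csv(out / "report" / "provenance.csv")
            state.result = EtlResult(cdm=CdmDatabase.read_csv(cdm_dir),
                                     report=report, provenance=provenance)

    def write_cdm():
        assert state.result is not None
        state.result.cdm.write_csv(out / "cdm")
        rep_dir = out / "report"
        rep_dir.mkdir(exist_ok=True)
        (rep_dir / "transform_report.json").write_text(
            json.dumps(state.result.report.to_dict(), indent=2,
                       sort_keys=True))
        state.result.provenance.to_csv(rep_dir / "provenance.csv",
                                       index=False)

    for stage in requested:
        t0 = time.time()
        if stage == "synth":
            state.source = generate_source(config.generator)
            state.source.write_csv(out / "source")
            manifest["stages"]["synth"] = {
                "rows": {k: len(v) for k, v in state.source.tables.items()}}
        elif stage == "vocab":
            need_vocab()
            manifest["stages"]["vocab"] = {
                "concepts": len(state.vocab.concept_frame())}
        elif stage == "etl":
            need_source()
            need_vocab()
            state.result = run_etl(state.source, state.vocab)
            write_cdm()
            decisions = getattr(state.result, "decisions", None)
            if decisions is not None:
                decisions.to_csv(out / "report" / "mapping_decisions.csv",
                                 index=False)
            manifest["stages"]["etl"] = {
                "rows": dict(state.result.report.target_rows)}
        elif stage == "derive":
            need_result()
            need_vocab()
            tables = apply_derive_stage(state.result, state.vocab)
            ddir = out / "derived"
            ddir.mkdir(exist_ok=True)
            for name, df in tables.items():
                df.to_csv(ddir / f"{name}.csv", index=False)
            write_cdm()
            manifest["stages"]["derive"] = {
                "rows": {k: len(v) for k, v in tables.items()}}
        elif stage == "nlp":
            need_result()
            need_vocab()
            templates = apply_nlp_stage(state.result, state.vocab)
            ndir = out / "nlp"
            ndir.mkdir(exist_ok=True)
            templates.to_csv(ndir / "section_templates.csv", index=False)
            write_cdm()
            manifest["stages"]["nlp"] = {
                "note_nlp_rows":
                    len(state.result.cdm.tables["note_nlp"]),
                "templates": len(templates)}
        elif stage == "qa":
            need_result()
            try:
                need_source()
                source = state.source
            except DependencyError:
                source = None
            report = evaluate(state.result, source=source,
                              shift_window=config.generator
                              .date_shift_window)
            qdir = out / "qa"
            qdir.mkdir(exist_ok=True)
            report.to_json(qdir / "quality_report.json")
            (qdir / "quality_report.txt").write_text(report.render_text())
            manifest["stages"]["qa"] = report.severity_counts()
        dt = round(time.time() - t0, 3)
        manifest["stages"][stage]["seconds"] = dt
        log.info("stage %s finished in %.2fs", stage, dt)

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
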
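"""Table layouts for the MIMIC-III v1.4 source schema and the OMOP CDM v5.3 target.

Columns are declared with a storage kind so that CSV round-trips are lossless:

* ``i``  -- nullable integer (pandas ``Int64``)
* ``f``  -- float
* ``s``  -- text (empty string on disk means null)
* ``t``  -- datetime, serialized ``YYYY-MM-DD HH:MM:SS``

Only the columns the transformation actually consumes or accounts for are
carried; the set mirrors the source layout closely enough that real exports
with these columns load unchanged.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# MIMIC-III source tables (26)
# ---------------------------------------------------------------------------

SOURCE_TABLES: dict[str, dict[str, str]] = {
    "patients": {
        "row_id": "i", "subject_id": "i", "gender": "s", "dob": "t",
        "dod": "t", "dod_hosp": "t", "expire_flag": "i",
    },
    "admissions": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "admittime": "t",
        "dischtime": "t", "deathtime": "t", "admission_type": "s",
        "admission_location": "s", "discharge_location": "s", "insurance": "s",
        "language": "s", "religion": "s", "marital_status": "s",
        "ethnicity": "s", "edregtime": "t", "edouttime": "t", "diagnosis": "s",
        "hospital_expire_flag": "i",
    },
    "transfers": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "dbsource": "s", "eventtype": "s", "prev_careunit": "s",
        "curr_careunit": "s", "prev_wardid": "i", "curr_wardid": "i",
        "intime": "t", "outtime": "t", "los": "f",
    },
    "services": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "transfertime": "t",
        "prev_service": "s", "curr_service": "s",
    },
    "icustays": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "dbsource": "s", "first_careunit": "s", "last_careunit": "s",
        "first_wardid": "i", "last_wardid": "i", "intime": "t",
        "outtime": "t", "los": "f",
    },
    "chartevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "itemid": "i", "charttime": "t", "storetime": "t", "cgid": "i",
        "value": "s", "valuenum": "f", "valueuom": "s", "warning": "i",
        "error": "i", "resultstatus": "s", "stopped": "s",
    },
    "labevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "itemid": "i",
        "charttime": "t", "value": "s", "valuenum": "f", "valueuom": "s",
        "flag": "s",
    },
    "outputevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "charttime": "t", "itemid": "i", "value": "f", "valueuom": "s",
        "storetime": "t", "cgid": "i", "stopped": "s", "newbottle": "i",
        "iserror": "i",
    },
    "microbiologyevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "chartdate": "t",
        "charttime": "t", "spec_itemid": "i", "spec_type_desc": "s",
        "org_itemid": "i", "org_name": "s", "isolate_num": "i",
        "ab_itemid": "i", "ab_name": "s", "dilution_text": "s",
        "dilution_comparison": "s", "dilution_value": "f",
        "interpretation": "s",
    },
    "prescriptions": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "startdate": "t", "enddate": "t", "drug_type": "s", "drug": "s",
        "drug_name_generic": "s", "formulary_drug_cd": "s", "gsn": "s",
        "ndc": "s", "prod_strength": "s", "dose_val_rx": "s",
        "dose_unit_rx": "s", "route": "s",
    },
    "inputevents_cv": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "charttime": "t", "itemid": "i", "amount": "f", "amountuom": "s",
        "rate": "f", "rateuom": "s", "storetime": "t", "cgid": "i",
        "orderid": "i", "linkorderid": "i", "stopped": "s",
        "originalroute": "s",
    },
    "inputevents_mv": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "starttime": "t", "endtime": "t", "itemid": "i", "amount": "f",
        "amountuom": "s", "rate": "f", "rateuom": "s", "storetime": "t",
        "cgid": "i", "orderid": "i", "linkorderid": "i",
        "ordercategoryname": "s", "patientweight": "f",
        "cancelreason": "i", "statusdescription": "s",
    },
    "procedureevents_mv": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "starttime": "t", "endtime": "t", "itemid": "i", "value": "f",
        "valueuom": "s", "location": "s", "storetime": "t", "cgid": "i",
        "orderid": "i", "linkorderid": "i", "ordercategoryname": "s",
        "cancelreason": "i", "statusdescription": "s",
    },
    "procedures_icd": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "seq_num": "i",
        "icd9_code": "s",
    },
    "diagnoses_icd": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "seq_num": "i",
        "icd9_code": "s",
    },
    "cptevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "costcenter": "s",
        "chartdate": "t", "cpt_cd": "s", "cpt_number": "i", "cpt_suffix": "s",
        "ticket_id_seq": "i", "sectionheader": "s", "subsectionheader": "s",
        "description": "s",
    },
    "noteevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "chartdate": "t",
        "charttime": "t", "storetime": "t", "category": "s",
        "description": "s", "cgid": "i", "iserror": "i", "text": "s",
    },
    "datetimeevents": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "icustay_id": "i",
        "itemid": "i", "charttime": "t", "storetime": "t", "cgid": "i",
        "value": "t", "valueuom": "s", "warning": "i", "error": "i",
        "resultstatus": "s", "stopped": "s",
    },
    "drgcodes": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i", "drg_type": "s",
        "drg_code": "s", "description": "s", "drg_severity": "i",
        "drg_mortality": "i",
    },
    "callout": {
        "row_id": "i", "subject_id": "i", "hadm_id": "i",
        "submit_wardid": "i", "curr_wardid": "i", "curr_careunit": "s",
        "callout_wardid": "i", "callout_service": "s", "request_tele": "i",
        "request_resp": "i", "callout_status": "s", "callout_outcome": "s",
        "createtime": "t", "outcometime": "t",
    },
    "caregivers": {
        "row_id": "i", "cgid": "i", "label": "s", "description": "s",
    },
    "d_items": {
        "row_id": "i", "itemid": "i", "label": "s", "abbreviation": "s",
        "dbsource": "s", "linksto": "s", "category": "s", "unitname": "s",
        "param_type": "s",
    },
    "d_labitems": {
        "row_id": "i", "itemid": "i", "label": "s", "fluid": "s",
        "category": "s", "loinc_code": "s",
    },
    "d_icd_diagnoses": {
        "row_id": "i", "icd9_code": "s", "short_title": "s", "long_title": "s",
    },
    "d_icd_procedures": {
        "row_id": "i", "icd9_code": "s", "short_title": "s", "long_title": "s",
    },
    "d_cpt": {
        "row_id": "i", "category": "i", "sectionrange": "s",
        "sectionheader": "s", "subsectionrange": "s", "subsectionheader": "s",
    },
}

#: the five source tables that carry an error / cancel flag
FLAGGED_TABLES = (
    "inputevents_mv", "chartevents", "procedureevents_mv",
    "noteevents", "datetimeevents",
)

#: per-table flag dialect: (column, flagged-value)
FLAG_DIALECT: dict[str, tuple[str, object]] = {
    "chartevents": ("error", 1),
    "datetimeevents": ("error", 1),
    "procedureevents_mv": ("statusdescription", "Rewritten"),
    "inputevents_mv": ("statusdescription", "Rewritten"),
    "noteevents": ("iserror", 1),
}

# ---------------------------------------------------------------------------
# OMOP CDM v5.3 target tables (clinical subset populated by the ETL)
# ---------------------------------------------------------------------------

CDM_TABLES: dict[str, dict[str, str]] = {
    "person": {
        "person_id": "i", "gender_concept_id": "i", "year_of_birth": "i",
        "month_of_birth": "i", "day_of_birth": "i", "birth_datetime": "t",
        "race_concept_id": "i", "ethnicity_concept_id": "i",
        "person_source_value": "s", "gender_source_value": "s",
        "race_source_value": "s", "ethnicity_source_value": "s",
    },
    "observation_period": {
        "observation_period_id": "i", "person_id": "i",
        "observation_period_start_date": "t",
        "observation_period_end_date": "t",
        "period_type_concept_id": "i",
    },
    "visit_occurrence": {
        "visit_occurrence_id": "i", "person_id": "i", "visit_concept_id": "i",
        "visit_start_datetime": "t", "visit_end_datetime": "t",
        "visit_type_concept_id": "i", "admitting_source_concept_id": "i",
        "admitting_source_value": "s", "discharge_to_concept_id": "i",
        "discharge_to_source_value": "s", "visit_source_value": "s",
    },
    "visit_detail": {
        "visit_detail_id": "i", "person_id": "i",
        "visit_detail_concept_id": "i", "visit_detail_start_datetime": "t",
        "visit_detail_end_datetime": "t", "visit_detail_type_concept_id": "i",
        "care_site_id": "i", "visit_detail_source_value": "s",
        "preceding_visit_detail_id": "i", "visit_occurrence_id": "i",
    },
    "care_site": {
        "care_site_id": "i", "care_site_name": "s",
        "place_of_service_concept_id": "i", "care_site_source_value": "s",
    },
    "death": {
        "person_id": "i", "death_date": "t", "death_datetime": "t",
        "death_type_concept_id": "i", "cause_concept_id": "i",
        "cause_source_value": "s",
    },
    "condition_occurrence": {
        "condition_occurrence_id": "i", "person_id": "i",
        "condition_concept_id": "i", "condition_start_datetime": "t",
        "condition_end_datetime": "t", "condition_type_concept_id": "i",
        "visit_occurrence_id": "i", "condition_source_value": "s",
        "condition_source_concept_id": "i",
    },
    "drug_exposure": {
        "drug_exposure_id": "i", "person_id": "i", "drug_concept_id": "i",
        "drug_exposure_start_datetime": "t", "drug_exposure_end_datetime": "t",
        "drug_type_concept_id": "i", "quantity": "f", "route_source_value": "s",
        "visit_occurrence_id": "i", "drug_source_value": "s",
        "drug_source_concept_id": "i", "dose_unit_source_value": "s",
    },
    "measurement": {
        "measurement_id": "i", "person_id": "i", "measurement_concept_id": "i",
        "measurement_datetime": "t", "measurement_type_concept_id": "i",
        "operator_concept_id": "i", "value_as_number": "f",
        "value_as_concept_id": "i", "unit_concept_id": "i",
        "unit_source_value": "s", "visit_occurrence_id": "i",
        "visit_detail_id": "i", "measurement_source_value": "s",
        "measurement_source_concept_id": "i", "value_source_value": "s",
    },
    "observation": {
        "observation_id": "i", "person_id": "i", "observation_concept_id": "i",
        "observation_datetime": "t", "observation_type_concept_id": "i",
        "value_as_number": "f", "value_as_string": "s",
        "value_as_concept_id": "i", "visit_occurrence_id": "i",
        "observation_source_value": "s", "observation_source_concept_id": "i",
    },
    "procedure_occurrence": {
        "procedure_occurrence_id": "i", "person_id": "i",
        "procedure_concept_id": "i", "procedure_datetime": "t",
        "procedure_end_datetime": "t", "procedure_type_concept_id": "i",
        "quantity": "f", "visit_occurrence_id": "i",
        "procedure_source_value": "s", "procedure_source_concept_id": "i",
    },
    "specimen": {
        "specimen_id": "i", "person_id": "i", "specimen_concept_id": "i",
        "specimen_type_concept_id": "i", "specimen_datetime": "t",
        "specimen_source_value": "s", "measurement_id": "i",
    },
    "note": {
        "note_id": "i", "person_id": "i", "note_datetime": "t",
        "note_type_concept_id": "i", "note_class_concept_id": "i",
        "note_title": "s", "note_text": "s", "encoding_concept_id": "i",
        "language_concept_id": "i", "provider_id": "i",
        "visit_occurrence_id": "i", "note_source_value": "s",
    },
    "note_nlp": {
        "note_nlp_id": "i", "note_id": "i", "section_concept_id": "i",
        "section_source_value": "s", "snippet": "s", "offset_begin": "i",
        "offset_end": "i", "lexical_variant": "s",
        "note_nlp_concept_id": "i", "note_nlp_source_concept_id": "i",
        "nlp_system": "s", "nlp_datetime": "t", "term_exists": "s",
        "value_as_number": "f", "unit_source_value": "s",
    },
    "provider": {
        "provider_id": "i", "provider_name": "s", "specialty_concept_id": "i",
        "specialty_source_value": "s", "provider_source_value": "s",
    },
    "cohort_attribute": {
        "cohort_definition_id": "i", "subject_id": "i",
        "cohort_start_date": "t", "cohort_end_date": "t",
        "attribute_definition_id": "i", "value_as_number": "f",
        "value_as_concept_id": "i",
    },
    "fact_relationship": {
        "domain_concept_id_1": "i", "fact_id_1": "i",
        "domain_concept_id_2": "i", "fact_id_2": "i",
        "relationship_concept_id": "i",
    },
    "concept": {
        "concept_id": "i", "concept_name": "s", "domain_id": "s",
        "vocabulary_id": "s", "concept_class_id": "s", "standard_concept": "s",
        "concept_code": "s", "valid_start_date": "t", "valid_end_date": "t",
    },
    "concept_relationship": {
        "concept_id_1": "i", "concept_id_2": "i", "relationship_id": "s",
    },
}

#: primary key column per CDM table (None -> no single-column key)
CDM_PRIMARY_KEYS: dict[str, str | None] = {
    "person": "person_id",
    "observation_period": "observation_period_id",
    "visit_occurrence": "visit_occurrence_id",
    "visit_detail": "visit_detail_id",
    "care_site": "care_site_id",
    "death": "person_id",
    "condition_occurrence": "condition_occurrence_id",
    "drug_exposure": "drug_exposure_id",
    "measurement": "measurement_id",
    "observation": "observation_id",
    "procedure_occurrence": "procedure_occurrence_id",
    "specimen": "specimen_id",
    "note": "note_id",
    "note_nlp": "note_nlp_id",
    "provider": "provider_id",
    "cohort_attribute": None,
    "fact_relationship": None,
    "concept": "concept_id",
    "concept_relationship": None,
}

DATETIME_FORMAT = "%Y-%m-%d %H:%M:%S"


def empty_table(schema: dict[str, str]) -> pd.DataFrame:
    """Typed empty DataFrame for a declared schema."""
    data = {}
    for col, kind in schema.items():
        if kind == "i":
            data[col] = pd.Series(dtype="Int64")
        elif kind == "f":
            data[col] = pd.Series(dtype="float64")
        elif kind == "t":
            data[col] = pd.Series(dtype="datetime64[ns]")
        else:
            data[col] = pd.Series(dtype="object")
    return pd.DataFrame(data)


def coerce_table(df: pd.DataFrame, schema: dict[str, str]) -> pd.DataFrame:
    """Coerce ``df`` to the declared schema, adding missing columns as null."""
    out = {}
    n = len(df)
    for col, kind in schema.items():
        if col in df.columns:
            s = df[col]
        else:
            s = pd.Series([pd.NA] * n, index=df.index)
        if kind == "i":
            out[col] = pd.Series(pd.array(s, dtype="Int64"), index=df.index)
        elif kind == "f":
            out[col] = pd.to_numeric(s, errors="coerce").astype("float64")
        elif kind == "t":
            out[col] = pd.to_datetime(s, errors="coerce")
        else:
            v = s.astype("object")
            v = v.where(~pd.isna(v), None)
            out[col] = v
    return pd.DataFrame(out, index=df.index).reset_index(drop=True)


class CsvParseError(ValueError):
    """Malformed CSV input; carries file, line and column context."""

    def __init__(self, path, line, column, message):
        self.path, self.line, self.column = str(path), line, column
        super().__init__(f"{path}:{line}:{column}: {message}")


def write_table_csv(df: pd.DataFrame, schema: dict[str, str], path: Path) -> None:
    """Write one table in the source CSV dialect (comma, double-quote, '' = null)."""
    out = df.copy()
    for col, kind in schema.items():
        if kind == "t":
            out[col] = out[col].dt.strftime(DATETIME_FORMAT)
    out.to_csv(path, index=False, na_rep="", lineterminator="\n")


def read_table_csv(path: Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read one table written by :func:`write_table_csv`."""
    try:
        raw = pd.read_csv(path, dtype="object", keep_default_na=False,
                          na_values=[""])
    except pd.errors.ParserError as exc:  # pragma: no cover - message plumbing
        raise CsvParseError(path, getattr(exc, "lineno", "?"), "?", str(exc))
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise CsvParseError(path, 1, ",".join(missing),
                            f"missing columns: {missing}")
    return coerce_table(raw, schema)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Field-by-field equality treating NaN/NaT/None as equal nulls."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        both_null = pd.isna(x) & pd.isna(y)
        if x.dtype.kind == "f" or y.dtype.kind == "f":
            eq = np.isclose(x.astype(float), y.astype(float), equal_nan=True)
        else:
            eq = (x == y).fillna(False) | both_null
        if not np.all(np.asarray(eq, dtype=bool) | np.asarray(both_null)):
            return False
    return True
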
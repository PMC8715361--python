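"""Structural ETL: move source rows into OMOP CDM v5.3 tables.

Design points mirrored from the transformation this package implements:

* one global integer sequence, starting at 0, allocates every clinical
  primary key, so ids are globally unique and monotone in emission order;
* every emitted row carries a provenance link back to its source row, and
  every dropped row is reported with a reason — input rows always equal
  provenance-linked rows plus dropped rows;
* rows tagged erroneous or cancelled in the five flagged source tables are
  filtered out (and only those);
* conceptual alignment runs before the structural move because the standard
  concept's domain decides the target table (chart items aligned to an
  Observation-domain concept land in OBSERVATION, not MEASUREMENT);
* ICU stays become one VISIT_DETAIL row per transfer segment — segments are
  never merged, even when readmission to the ICU happens within 24 hours —
  and emergency-department time is a first-class leading segment;
* audit timestamps (``storetime`` and friends) are dropped by the mapping
  specification, never silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dictionaries as dd
from .derive import parse_lab_value, normalize_temperature, OPERATOR_CONCEPTS
from .schemas import (CDM_TABLES, CDM_PRIMARY_KEYS, FLAG_DIALECT,
                      SOURCE_TABLES, coerce_table, empty_table, frames_equal,
                      read_table_csv, write_table_csv)
from .source import SourceDatabase, SourceIntegrityError
from .vocabulary import VocabularyStore, MappingDecision

# OMOP domain concept ids used in FACT_RELATIONSHIP
DOMAIN_MEASUREMENT = 21
DOMAIN_VISIT_DETAIL = 8
DOMAIN_CARE_SITE = 57
DOMAIN_DRUG = 13

GENDER_CONCEPTS = {"F": 8532, "M": 8507}
RACE_CONCEPTS = {"WHITE": 8527, "BLACK/AFRICAN AMERICAN": 8516, "ASIAN": 8515}
ETHNICITY_CONCEPTS = {"HISPANIC OR LATINO": 38003563}
UNIT_CONCEPTS = {
    "Deg. C": 8582, "Deg. F": 9289, "bpm": 8541, "insp/min": 8541,
    "mmHg": 8876, "%": 8554, "mg/dL": 8840, "mEq/L": 9557, "g/dL": 8713,
    "K/uL": 9531, "ng/mL": 8842, "mL": 8587, "cm": 9530, "kg": 9529,
    "units": 0, "points": 0, "lbs": 9529,  # pounds normalized to kg
}
EHR_TYPE = 32817
VISIT_TYPE = 44818518
RX_TYPE = 38000177
ICU_DETAIL_CONCEPT = 32037
INPATIENT_VISIT = 9201
ER_INPATIENT_VISIT = 262
POS_INPATIENT = 8717
POS_ER = 8870


class EtlIntegrityError(RuntimeError):
    """A CDM invariant failed during or after the transformation."""


class GlobalSequence:
    """Strictly increasing id allocator shared by all tables in one run."""

    def __init__(self, start: int = 0):
        self._next = int(start)

    @property
    def next_value(self) -> int:
        return self._next

    def allocate(self) -> int:
        v = self._next
        self._next += 1
        return v

    def take(self, n: int) -> np.ndarray:
        block = np.arange(self._next, self._next + int(n), dtype="int64")
        self._next += int(n)
        return block


@dataclass
class TransformReport:
    """Row accounting per source table plus target-table tallies."""

    input_rows: dict[str, int] = field(default_factory=dict)
    linked_rows: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, dict[str, int]] = field(default_factory=dict)
    target_rows: dict[str, int] = field(default_factory=dict)
    flags: dict[str, int] = field(default_factory=dict)  # data-quality notes

    def drop(self, table: str, reason: str, count: int) -> None:
        if count:
            self.dropped.setdefault(table, {})
            self.dropped[table][reason] = \
                self.dropped[table].get(reason, 0) + int(count)

    def dropped_total(self, table: str) -> int:
        return sum(self.dropped.get(table, {}).values())

    def note(self, flag: str, count: int = 1) -> None:
        if count:
            self.flags[flag] = self.flags.get(flag, 0) + int(count)

    def to_dict(self) -> dict:
        return {"input_rows": self.input_rows,
                "linked_rows": self.linked_rows,
                "dropped": self.dropped, "target_rows": self.target_rows,
                "flags": self.flags}


@dataclass
class CdmDatabase:
    """The populated OMOP v5.3 clinical tables."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        for name, schema in CDM_TABLES.items():
            if name not in self.tables:
                self.tables[name] = empty_table(schema)
            else:
                self.tables[name] = coerce_table(self.tables[name], schema)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, schema in CDM_TABLES.items():
            write_table_csv(self.tables[name], schema,
                            path / f"{name.upper()}.csv")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "CdmDatabase":
        path = Path(path)
        tables = {}
        for name, schema in CDM_TABLES.items():
            f = path / f"{name.upper()}.csv"
            if f.exists():
                tables[name] = read_table_csv(f, schema)
        return cls(tables)

    def equals(self, other: "CdmDatabase") -> bool:
        return all(frames_equal(self.tables[n], other.tables[n])
                   for n in CDM_TABLES)

    # -- integrity ---------------------------------------------------------

    def integrity_violations(self) -> list[str]:
        """Primary-key, foreign-key and non-null violations, empty if clean."""
        v: list[str] = []
        t = self.tables
        for name, pk in CDM_PRIMARY_KEYS.items():
            if pk is None or name == "death":
                continue
            col = t[name][pk]
            if col.isna().any():
                v.append(f"{name}.{pk}: null primary key")
            if col.duplicated().any():
                v.append(f"{name}.{pk}: duplicate primary key")
        if t["death"]["person_id"].duplicated().any():
            v.append("death.person_id: duplicate primary key")
        persons = set(t["person"]["person_id"].dropna())
        visits = set(t["visit_occurrence"]["visit_occurrence_id"].dropna())
        details = set(t["visit_detail"]["visit_detail_id"].dropna())
        sites = set(t["care_site"]["care_site_id"].dropna())
        for name in ("visit_occurrence", "visit_detail", "death",
                     "condition_occurrence", "drug_exposure", "measurement",
                     "observation", "procedure_occurrence", "specimen",
                     "note", "observation_period"):
            refs = set(t[name]["person_id"].dropna())
            if not refs <= persons:
                v.append(f"{name}.person_id: {len(refs - persons)} dangling")
        for name in ("visit_detail", "condition_occurrence", "drug_exposure",
                     "measurement", "observation", "procedure_occurrence",
                     "note"):
            col = t[name]["visit_occurrence_id"].dropna()
            refs = set(col)
            if not refs <= visits:
                v.append(f"{name}.visit_occurrence_id: "
                         f"{len(refs - visits)} dangling")
        refs = set(t["measurement"]["visit_detail_id"].dropna())
        if not refs <= details:
            v.append(f"measurement.visit_detail_id: {len(refs-details)} "
                     "dangling")
        refs = set(t["visit_detail"]["care_site_id"].dropna())
        if not refs <= sites:
            v.append(f"visit_detail.care_site_id: {len(refs-sites)} dangling")
        refs = set(t["visit_detail"]["preceding_visit_detail_id"].dropna())
        if not refs <= details:
            v.append("visit_detail.preceding_visit_detail_id: dangling")
        refs = set(t["specimen"]["measurement_id"].dropna())
        meas = set(t["measurement"]["measurement_id"].dropna())
        if not refs <= meas:
            v.append(f"specimen.measurement_id: {len(refs-meas)} dangling")
        notes = set(t["note"]["note_id"].dropna())
        refs = set(t["note_nlp"]["note_id"].dropna())
        if not refs <= notes:
            v.append(f"note_nlp.note_id: {len(refs-notes)} dangling")
        fact_domains = {DOMAIN_MEASUREMENT: meas, DOMAIN_VISIT_DETAIL: details,
                        DOMAIN_CARE_SITE: sites,
                        DOMAIN_DRUG: set(t["drug_exposure"]
                                         ["drug_exposure_id"].dropna())}
        fr = t["fact_relationship"]
        for side in (1, 2):
            for dom, pool in fact_domains.items():
                refs = set(fr.loc[fr[f"domain_concept_id_{side}"] == dom,
                                  f"fact_id_{side}"].dropna())
                if not refs <= pool:
                    v.append(f"fact_relationship.fact_id_{side} (domain "
                             f"{dom}): {len(refs - pool)} dangling")
        concepts = set(t["concept"]["concept_id"].dropna())
        for name, df in t.items():
            if name in ("concept", "concept_relationship"):
                continue
            for col in [c for c in df.columns if c.endswith("_concept_id")]:
                if df[col].isna().any():
                    v.append(f"{name}.{col}: null concept id")
                refs = set(df[col].dropna()) - {0}
                if not refs <= concepts:
                    v.append(f"{name}.{col}: {len(refs - concepts)} "
                             "unknown concept ids")
        required_datetimes = {
            "visit_occurrence": "visit_start_datetime",
            "visit_detail": "visit_detail_start_datetime",
            "measurement": "measurement_datetime",
            "observation": "observation_datetime",
            "condition_occurrence": "condition_start_datetime",
            "drug_exposure": "drug_exposure_start_datetime",
            "procedure_occurrence": "procedure_datetime",
            "specimen": "specimen_datetime",
            "note": "note_datetime",
        }
        for name, col in required_datetimes.items():
            if t[name][col].isna().any():
                v.append(f"{name}.{col}: null required datetime")
        return v

    def sequence_ids(self) -> np.ndarray:
        """All sequence-allocated primary keys, in table emission order."""
        out = []
        for name, pk in CDM_PRIMARY_KEYS.items():
            if pk is None or name in ("concept", "death"):
                continue
            out.append(self.tables[name][pk].to_numpy(dtype="int64"))
        return np.concatenate(out) if out else np.array([], dtype="int64")


@dataclass
class EtlResult:
    cdm: CdmDatabase
    report: TransformReport
    provenance: pd.DataFrame  # source_table, source_row_id, cdm_table, cdm_row_id


def allocate_id(seq: GlobalSequence) -> int:
    """Next value of the shared global sequence."""
    return seq.allocate()


def filter_invalid(df: pd.DataFrame, table: str
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows tagged erroneous/cancelled in the five flagged tables."""
    if table not in FLAG_DIALECT:
        return df, df.iloc[0:0]
    col, bad = FLAG_DIALECT[table]
    mask = df[col] == bad
    return df[~mask.fillna(False)], df[mask.fillna(False)]


# ---------------------------------------------------------------------------
# The transformation
# ---------------------------------------------------------------------------

class _Etl:
    """One ETL run; methods populate ``self.out`` table by table."""

    def __init__(self, source: SourceDatabase, vocab: VocabularyStore):
        self.src = source
        self.vocab = vocab
        self.seq = GlobalSequence()
        self.report = TransformReport()
        self.out: dict[str, pd.DataFrame] = {}
        self._prov: list[pd.DataFrame] = []
        self.person_of: dict[int, int] = {}
        self.visit_of: dict[int, int] = {}
        self.decisions: dict[tuple[str, str], MappingDecision] = {}
        self._kept: dict[str, pd.DataFrame] = {}
        self._micro_groups: list[tuple[int, list[int]]] = []
        self._obs_buffers: list[pd.DataFrame] = []
        self._mv_solution: pd.DataFrame | None = None

    # -- helpers -----------------------------------------------------------

    def link(self, source_table: str, source_row_ids, cdm_table: str,
             cdm_row_ids) -> None:
        self._prov.append(pd.DataFrame({
            "source_table": source_table,
            "source_row_id": np.asarray(source_row_ids, dtype="int64"),
            "cdm_table": cdm_table,
            "cdm_row_id": np.asarray(cdm_row_ids, dtype="int64")}))

    def _register_and_align(self, name: str, domain: str, source_table: str,
                            code: str, code_vocab: str | None = None
                            ) -> MappingDecision:
        local = self.vocab.register_local_concept(
            name, domain, source_table, code=code, code_vocabulary=code_vocab)
        decision = self.vocab.align_concept(local)
        self.decisions[(source_table, code)] = decision
        return decision

    def decision_frame(self) -> pd.DataFrame:
        rows = [dict(source_table=t, local_code=c,
                     local_concept_id=d.local_concept_id,
                     standard_concept_id=d.standard_concept_id,
                     case_tag=d.case_tag, score=d.score, comment=d.comment)
                for (t, c), d in sorted(self.decisions.items())]
        return pd.DataFrame(rows)

    # -- vocabulary phase --------------------------------------------------

    def align_dictionaries(self) -> None:
        v = self.vocab
        for name in ("Bed Transfer", "Room Transfer",
                     "Emergency Department Stay", "Ward Stay",
                     "Intensive Care Unit Stay", "Labs - Chemistry",
                     "Labs - Culture Organisms", "Labs - Culture Sensitivity",
                     "Chart - Vital Signs", "Chart - Laboratory",
                     "Note-derived Value", "Derived Value", "Severity Score",
                     "Output Events", "Callout Request",
                     "Has susceptibility test", "Susceptibility test of",
                     "Drug in solution", "Solution contains drug",
                     "Located at care site", "Care site of visit detail",
                     "Datetime Events", "Drg Code"):
            v.register_extension_concept(name)

        di = self.src["d_items"]
        domain_of_linksto = {
            "chartevents": "Measurement", "datetimeevents": "Observation",
            "outputevents": "Measurement", "inputevents_cv": "Drug",
            "inputevents_mv": "Drug", "procedureevents_mv": "Procedure",
            "microbiologyevents": "Measurement"}
        for row in di.itertuples(index=False):
            decision = self._register_and_align(
                f"{row.label} | {row.category}" if row.category
                else str(row.label),
                domain_of_linksto.get(row.linksto, "Measurement"),
                "d_items", str(row.itemid))
            self.link("d_items", [row.row_id], "concept",
                      [decision.local_concept_id])

        for row in self.src["d_labitems"].itertuples(index=False):
            name = " | ".join(x for x in (row.label, row.fluid, row.category)
                              if x)
            decision = self._register_and_align(
                name, "Measurement", "d_labitems", str(row.itemid),
                code_vocab="LOINC" if row.loinc_code else None)
            if row.loinc_code:
                # alignment keys on the item's LOINC code, not the itemid
                local = self.vocab.register_local_concept(
                    name, "Measurement", "d_labitems",
                    code=str(row.loinc_code), code_vocabulary="LOINC")
                d2 = self.vocab.align_concept(local)
                self.decisions[("d_labitems", str(row.itemid))] = d2
                decision = d2
            self.link("d_labitems", [row.row_id], "concept",
                      [decision.local_concept_id])

        for table, vocab_id, code_col in (
                ("d_icd_diagnoses", "ICD9CM", "icd9_code"),
                ("d_icd_procedures", "ICD9Proc", "icd9_code")):
            domain = "Condition" if table == "d_icd_diagnoses" else "Procedure"
            for row in self.src[table].itertuples(index=False):
                decision = self._register_and_align(
                    row.long_title, domain, table, str(getattr(row, code_col)),
                    code_vocab=vocab_id)
                self.link(table, [row.row_id], "concept",
                          [decision.local_concept_id])

        for row in self.src["d_cpt"].itertuples(index=False):
            local = self.vocab.register_local_concept(
                row.subsectionheader or row.sectionheader, "Procedure",
                "d_cpt", code=str(row.subsectionrange))
            self.link("d_cpt", [row.row_id], "concept", [local.concept_id])

        cpt_codes = self.src["cptevents"]["cpt_cd"].dropna().unique()
        for code in sorted(cpt_codes):
            self._register_and_align(f"CPT {code}", "Procedure", "cptevents",
                                     str(code), code_vocab="CPT4")

        for drug, generic, ndc, _route in dd.FORMULARY:
            present = self.src["prescriptions"]["drug"] == drug
            if not present.any():
                continue
            self._register_and_align(generic or drug, "Drug", "prescriptions",
                                     str(ndc) if ndc else drug,
                                     code_vocab="NDC" if ndc else None)

    def _decide(self, source_table: str, code) -> MappingDecision | None:
        return self.decisions.get((source_table, str(code)))

    def _std_map(self, source_table: str) -> dict[str, MappingDecision]:
        return {c: d for (t, c), d in self.decisions.items()
                if t == source_table}

    # -- filtering ---------------------------------------------------------

    def filter_sources(self) -> None:
        for name in SOURCE_TABLES:
            df = self.src[name]
            self.report.input_rows[name] = len(df)
            kept, dropped = filter_invalid(df, name)
            self._kept[name] = kept
            self.report.drop(name, "flagged_invalid", len(dropped))
        icu = self.src["icustays"]
        self.report.drop("icustays", "derived_source_not_transformed",
                         len(icu))

    # -- person / death / observation period -------------------------------

    def etl_person(self) -> None:
        pats = self._kept["patients"]
        adms = self._kept["admissions"].sort_values("admittime")
        latest = adms.groupby("subject_id").last()
        rows = []
        prov_ids = []
        for row in pats.itertuples(index=False):
            pid = self.seq.allocate()
            self.person_of[int(row.subject_id)] = pid
            adm = latest.loc[int(row.subject_id)] \
                if int(row.subject_id) in latest.index else None
            eth = adm["ethnicity"] if adm is not None else None
            rows.append(dict(
                person_id=pid,
                gender_concept_id=GENDER_CONCEPTS.get(row.gender, 0),
                year_of_birth=row.dob.year if pd.notna(row.dob) else None,
                month_of_birth=row.dob.month if pd.notna(row.dob) else None,
                day_of_birth=row.dob.day if pd.notna(row.dob) else None,
                birth_datetime=row.dob,
                race_concept_id=RACE_CONCEPTS.get(eth, 0) if eth else 0,
                ethnicity_concept_id=ETHNICITY_CONCEPTS.get(eth, 0)
                if eth else 0,
                person_source_value=str(row.subject_id),
                gender_source_value=row.gender,
                race_source_value=eth, ethnicity_source_value=eth))
            prov_ids.append((int(row.row_id), pid))
        self.out["person"] = pd.DataFrame(rows)
        if prov_ids:
            src_ids, cdm_ids = zip(*prov_ids)
            self.link("patients", src_ids, "person", cdm_ids)

        # observation period: first to last recorded admission interval
        if len(adms):
            grp = adms.groupby("subject_id").agg(
                start=("admittime", "min"), end=("dischtime", "max"),
                row_id=("row_id", "first"))
            ids = self.seq.take(len(grp))
            self.out["observation_period"] = pd.DataFrame({
                "observation_period_id": ids,
                "person_id": [self.person_of[s] for s in grp.index],
                "observation_period_start_date": grp["start"].values,
                "observation_period_end_date": grp["end"].values,
                "period_type_concept_id": EHR_TYPE})

        # death: discharge flag takes precedence over patient-level date
        deaths = []
        death_prov = []
        by_subject = self._kept["admissions"].groupby("subject_id")
        for row in pats.itertuples(index=False):
            sid = int(row.subject_id)
            hosp_death = None
            if sid in by_subject.groups:
                adm_rows = by_subject.get_group(sid)
                flagged = adm_rows[adm_rows["hospital_expire_flag"] == 1]
                if len(flagged):
                    hosp_death = flagged.iloc[-1]
            if hosp_death is not None:
                when = hosp_death["deathtime"]
                if pd.isna(when):
                    when = hosp_death["dischtime"]
                if pd.notna(row.dod) and pd.notna(when) and row.dod != when:
                    self.report.note("death_source_disagreement")
            elif pd.notna(row.dod):
                when = row.dod
            else:
                continue
            deaths.append(dict(
                person_id=self.person_of[sid],
                death_date=when.normalize() if pd.notna(when) else when,
                death_datetime=when, death_type_concept_id=EHR_TYPE,
                cause_concept_id=0, cause_source_value=None))
            death_prov.append(int(row.row_id))
        self.out["death"] = pd.DataFrame(deaths)
        if death_prov:
            self.link("patients", death_prov, "death",
                      [d["person_id"] for d in deaths])

    # -- visits ------------------------------------------------------------

    def etl_visit_occurrence(self) -> None:
        adms = self._kept["admissions"]
        n = len(adms)
        ids = self.seq.take(n)
        self.visit_of = dict(zip(adms["hadm_id"].astype(int), ids))
        emergency = adms["edregtime"].notna()
        svc = self._kept["services"].drop_duplicates("hadm_id") \
            .set_index("hadm_id")["curr_service"]
        service = adms["hadm_id"].map(svc)
        suffix = service.map(lambda s: f"/{s}" if isinstance(s, str) else "")
        source_value = adms["admission_type"].fillna("UNKNOWN").astype(str) \
            + suffix.astype(str)
        start = adms["edregtime"].where(emergency, adms["admittime"])
        implausible = (adms["dischtime"] < adms["admittime"]).fillna(False)
        self.report.note("implausible_interval", int(implausible.sum()))
        self.out["visit_occurrence"] = pd.DataFrame({
            "visit_occurrence_id": ids,
            "person_id": adms["subject_id"].map(self.person_of),
            "visit_concept_id": np.where(emergency, ER_INPATIENT_VISIT,
                                         INPATIENT_VISIT),
            "visit_start_datetime": start,
            "visit_end_datetime": adms["dischtime"],
            "visit_type_concept_id": VISIT_TYPE,
            "admitting_source_concept_id": 0,
            "admitting_source_value": adms["admission_location"],
            "discharge_to_concept_id": 0,
            "discharge_to_source_value": adms["discharge_location"],
            "visit_source_value": source_value})
        self.link("admissions", adms["row_id"], "visit_occurrence", ids)

    def _care_site(self, name: str, pos: int, cache: dict[str, int],
                   rows: list[dict]) -> int:
        if name not in cache:
            csid = self.seq.allocate()
            cache[name] = csid
            rows.append(dict(care_site_id=csid, care_site_name=name,
                             place_of_service_concept_id=pos,
                             care_site_source_value=name))
        return cache[name]

    def etl_visit_detail(self) -> None:
        vocab = self.vocab
        er_concept = vocab.extension_id("Emergency Department Stay")
        ward_concept = vocab.extension_id("Ward Stay")
        cache: dict[str, int] = {}
        site_rows: list[dict] = []
        detail_rows: list[dict] = []
        prov: list[tuple[str, int, int]] = []

        transfers = self._kept["transfers"]
        by_hadm = dict(tuple(transfers.groupby("hadm_id")))
        adms = self._kept["admissions"]
        for adm in adms.itertuples(index=False):
            hadm = int(adm.hadm_id)
            pid = self.person_of[int(adm.subject_id)]
            vid = self.visit_of[hadm]
            segments: list[tuple] = []  # (start, end, concept, site, src, rid)
            if pd.notna(adm.edregtime):
                site = self._care_site("Emergency Department", POS_ER,
                                       cache, site_rows)
                segments.append((adm.edregtime, adm.edouttime, er_concept,
                                 site, "admissions", int(adm.row_id)))
            tr = by_hadm.get(hadm)
            if tr is not None and len(tr):
                tr = tr.sort_values("intime")
                if (tr["intime"].iloc[1:].values
                        < tr["outtime"].iloc[:-1].values).any():
                    raise EtlIntegrityError(
                        f"overlapping transfers in admission {hadm}")
                for row in tr.itertuples(index=False):
                    unit = row.curr_careunit
                    if pd.notna(unit) and unit:
                        concept = ICU_DETAIL_CONCEPT
                        site = self._care_site(str(unit), ICU_DETAIL_CONCEPT,
                                               cache, site_rows)
                    else:
                        concept = ward_concept
                        site = self._care_site(
                            f"Ward {int(row.curr_wardid)}"
                            if pd.notna(row.curr_wardid) else "Ward unknown",
                            POS_INPATIENT, cache, site_rows)
                    segments.append((row.intime, row.outtime, concept, site,
                                     "transfers", int(row.row_id)))
            else:
                # no transfer rows: one synthetic segment covers the admission
                site = self._care_site("Ward unknown", POS_INPATIENT,
                                       cache, site_rows)
                segments.append((adm.admittime, adm.dischtime, ward_concept,
                                 site, "admissions", int(adm.row_id)))
            preceding = None
            for start, end, concept, site, src_table, src_row in segments:
                did = self.seq.allocate()
                detail_rows.append(dict(
                    visit_detail_id=did, person_id=pid,
                    visit_detail_concept_id=concept,
                    visit_detail_start_datetime=start,
                    visit_detail_end_datetime=end,
                    visit_detail_type_concept_id=VISIT_TYPE,
                    care_site_id=site,
                    visit_detail_source_value=None,
                    preceding_visit_detail_id=preceding,
                    visit_occurrence_id=vid))
                prov.append((src_table, src_row, did))
                preceding = did

        # services annotate the stay: each service row becomes a care site
        # link for its admission (Table CARE_SITE sources transfers+services)
        for row in self._kept["services"].itertuples(index=False):
            site = self._care_site(f"Service {row.curr_service}",
                                   POS_INPATIENT, cache, site_rows)
            prov.append(("services", int(row.row_id), site))

        self.out["visit_detail"] = pd.DataFrame(detail_rows)
        self.out["care_site"] = pd.DataFrame(site_rows)
        for table in ("admissions", "transfers"):
            rows = [(r, d) for t, r, d in prov if t == table]
            if rows:
                src, det = zip(*rows)
                self.link(table, src, "visit_detail", det)
        svc = [(r, d) for t, r, d in prov if t == "services"]
        if svc:
            src, det = zip(*svc)
            self.link("services", src, "care_site", det)

    # -- measurements ------------------------------------------------------

    def _measurement_frame(self, n: int) -> dict:
        return dict(measurement_id=self.seq.take(n))

    def etl_measurement(self) -> None:
        frames: list[pd.DataFrame] = []
        spec_sources: list[pd.DataFrame] = []

        # chartevents: route by aligned domain, normalize temperatures
        ce = self._kept["chartevents"]
        item_meta = self.src["d_items"].set_index("itemid")
        decisions = self._std_map("d_items")
        if len(ce):
            std = ce["itemid"].map(
                {int(c): d.standard_concept_id for c, d in decisions.items()})
            local = ce["itemid"].map(
                {int(c): d.local_concept_id for c, d in decisions.items()})
            present = set(ce["itemid"].dropna().astype(int))
            route = ce["itemid"].map(
                {int(c): self.vocab.domain_route(d, "MEASUREMENT")
                 for c, d in decisions.items() if int(c) in present})
            category = ce["itemid"].map(item_meta["category"])
            label = ce["itemid"].map(item_meta["label"])
            is_f = ce["valueuom"].eq("Deg. F") & std.eq(3020891)
            is_lb = ce["valueuom"].eq("lbs") & std.eq(3025315)
            vnum = ce["valuenum"].astype(float)
            vnum = np.where(is_f, ((vnum - 32.0) * 5.0 / 9.0).round(1), vnum)
            vnum = np.where(is_lb, (vnum * 0.453592).round(1), vnum)
            unit_src = ce["valueuom"].where(~(is_f | is_lb),
                                            pd.Series(np.where(is_f, "Deg. C",
                                                               "kg"),
                                                      index=ce.index))
            unit_concept = unit_src.map(UNIT_CONCEPTS).fillna(0)
            mtype = np.where(category.eq("Labs"),
                             self.vocab.extension_id("Chart - Laboratory"),
                             self.vocab.extension_id("Chart - Vital Signs"))
            base = pd.DataFrame({
                "person_id": ce["subject_id"].map(self.person_of),
                "measurement_concept_id": std.fillna(0),
                "measurement_datetime": ce["charttime"],
                "measurement_type_concept_id": mtype,
                "operator_concept_id": OPERATOR_CONCEPTS["="],
                "value_as_number": vnum,
                "value_as_concept_id": 0,
                "unit_concept_id": unit_concept,
                "unit_source_value": unit_src,
                "visit_occurrence_id": ce["hadm_id"].map(self.visit_of),
                "measurement_source_value": label,
                "measurement_source_concept_id": local.fillna(0),
                "value_source_value": ce["value"],
                "_src_table": "chartevents",
                "_src_row": ce["row_id"].astype("int64"),
                "_route": route.fillna("MEASUREMENT"),
                "_is_lab": category.eq("Labs"),
            })
            to_obs = base[base["_route"] == "OBSERVATION"]
            frames.append(base[base["_route"] != "OBSERVATION"])
            if len(to_obs):
                self._obs_buffers.append(pd.DataFrame({
                    "person_id": to_obs["person_id"],
                    "observation_concept_id":
                        to_obs["measurement_concept_id"],
                    "observation_datetime": to_obs["measurement_datetime"],
                    "observation_type_concept_id":
                        to_obs["measurement_type_concept_id"],
                    "value_as_number": to_obs["value_as_number"],
                    "value_as_string": to_obs["value_source_value"],
                    "value_as_concept_id": 0,
                    "visit_occurrence_id": to_obs["visit_occurrence_id"],
                    "observation_source_value":
                        to_obs["measurement_source_value"],
                    "observation_source_concept_id":
                        to_obs["measurement_source_concept_id"],
                    "_src_table": "chartevents",
                    "_src_row": to_obs["_src_row"]}))

        # labevents: textual values run through the value parser
        le = self._kept["labevents"]
        lab_dec = self._std_map("d_labitems")
        if len(le):
            std = le["itemid"].map(
                {int(c): d.standard_concept_id for c, d in lab_dec.items()})
            local = le["itemid"].map(
                {int(c): d.local_concept_id for c, d in lab_dec.items()})
            lab_meta = self.src["d_labitems"].set_index("itemid")
            label = le["itemid"].map(lab_meta["label"])
            fluid = le["itemid"].map(lab_meta["fluid"])
            vnum = le["valuenum"].astype(float).to_numpy()
            op = np.full(len(le), OPERATOR_CONCEPTS["="], dtype="int64")
            unit_src = le["valueuom"].copy()
            textual = le["valuenum"].isna() & le["value"].notna()
            for i in np.flatnonzero(textual.to_numpy()):
                parse = parse_lab_value(le["value"].iloc[i])
                if parse.number is not None:
                    vnum[i] = parse.number
                    op[i] = OPERATOR_CONCEPTS[parse.operator]
                    if parse.unit:
                        unit_src.iloc[i] = parse.unit
            frames.append(pd.DataFrame({
                "person_id": le["subject_id"].map(self.person_of),
                "measurement_concept_id": std.fillna(0),
                "measurement_datetime": le["charttime"],
                "measurement_type_concept_id":
                    self.vocab.extension_id("Labs - Chemistry"),
                "operator_concept_id": op,
                "value_as_number": vnum,
                "value_as_concept_id": 0,
                "unit_concept_id": unit_src.map(UNIT_CONCEPTS).fillna(0),
                "unit_source_value": unit_src,
                "visit_occurrence_id": le["hadm_id"].map(self.visit_of),
                "measurement_source_value": label,
                "measurement_source_concept_id": local.fillna(0),
                "value_source_value": le["value"],
                "_src_table": "labevents",
                "_src_row": le["row_id"].astype("int64"),
                "_route": "MEASUREMENT", "_is_lab": True,
                "_specimen_fluid": fluid}))

        # outputevents
        oe = self._kept["outputevents"]
        if len(oe):
            std = oe["itemid"].map(
                {int(c): d.standard_concept_id for c, d in decisions.items()})
            local = oe["itemid"].map(
                {int(c): d.local_concept_id for c, d in decisions.items()})
            frames.append(pd.DataFrame({
                "person_id": oe["subject_id"].map(self.person_of),
                "measurement_concept_id": std.fillna(0),
                "measurement_datetime": oe["charttime"],
                "measurement_type_concept_id":
                    self.vocab.extension_id("Output Events"),
                "operator_concept_id": OPERATOR_CONCEPTS["="],
                "value_as_number": oe["value"].astype(float),
                "value_as_concept_id": 0,
                "unit_concept_id": oe["valueuom"].map(UNIT_CONCEPTS).fillna(0),
                "unit_source_value": oe["valueuom"],
                "visit_occurrence_id": oe["hadm_id"].map(self.visit_of),
                "measurement_source_value":
                    oe["itemid"].map(item_meta["label"]),
                "measurement_source_concept_id": local.fillna(0),
                "value_source_value": oe["value"].astype(str),
                "_src_table": "outputevents",
                "_src_row": oe["row_id"].astype("int64"),
                "_route": "MEASUREMENT", "_is_lab": False}))

        # microbiology: organism rows then susceptibility rows
        me = self._kept["microbiologyevents"]
        if len(me):
            org_rows = me[me["ab_itemid"].isna()]
            sens_rows = me[me["ab_itemid"].notna()]
            manual = self.vocab.manual_entries()
            spec_std = {int(c): t for (tab, c), (t, _s, _c) in
                        ((k, v) for k, v in manual.items())
                        if False}  # placeholder, replaced below
            spec_std = {i: manual.get(("d_items", str(i)), (0, 0, ""))[0]
                        for i in me["spec_itemid"].dropna().unique()}
            org_std = {i: manual.get(("d_items", str(i)), (0, 0, ""))[0]
                       for i in me["org_itemid"].dropna().unique()}
            ab_std = {i: manual.get(("d_items", str(i)), (0, 0, ""))[0]
                      for i in me["ab_itemid"].dropna().unique()}
            interp = {k[1]: v[0] for k, v in manual.items()
                      if k[0] == "micro_interpretation"}
            org_local = {int(c): d.local_concept_id
                         for c, d in decisions.items()}
            if len(org_rows):
                frames.append(pd.DataFrame({
                    "person_id": org_rows["subject_id"].map(self.person_of),
                    "measurement_concept_id":
                        org_rows["spec_itemid"].map(spec_std).fillna(0),
                    "measurement_datetime": org_rows["charttime"],
                    "measurement_type_concept_id":
                        self.vocab.extension_id("Labs - Culture Organisms"),
                    "operator_concept_id": OPERATOR_CONCEPTS["="],
                    "value_as_number": np.nan,
                    "value_as_concept_id":
                        org_rows["org_itemid"].map(org_std).fillna(0),
                    "unit_concept_id": 0, "unit_source_value": None,
                    "visit_occurrence_id":
                        org_rows["hadm_id"].map(self.visit_of),
                    "measurement_source_value": org_rows["spec_type_desc"],
                    "measurement_source_concept_id":
                        org_rows["spec_itemid"].map(org_local).fillna(0),
                    "value_source_value": org_rows["org_name"],
                    "_src_table": "microbiologyevents",
                    "_src_row": org_rows["row_id"].astype("int64"),
                    "_route": "MEASUREMENT", "_is_lab": False,
                    "_micro_fluid": org_rows["spec_type_desc"],
                    "_micro_key": org_rows["hadm_id"].astype(str) + "|"
                        + org_rows["spec_itemid"].astype(str) + "|"
                        + org_rows["org_itemid"].astype(str) + "|"
                        + org_rows["charttime"].astype(str),
                    "_micro_role": "organism"}))
            if len(sens_rows):
                ops = sens_rows["dilution_comparison"].map(
                    {"<=": OPERATOR_CONCEPTS["≤"], ">=": OPERATOR_CONCEPTS["≥"],
                     "=": OPERATOR_CONCEPTS["="], "<": OPERATOR_CONCEPTS["<"],
                     ">": OPERATOR_CONCEPTS[">"]}).fillna(
                         OPERATOR_CONCEPTS["="])
                frames.append(pd.DataFrame({
                    "person_id": sens_rows["subject_id"].map(self.person_of),
                    "measurement_concept_id":
                        sens_rows["ab_itemid"].map(ab_std).fillna(0),
                    "measurement_datetime": sens_rows["charttime"],
                    "measurement_type_concept_id":
                        self.vocab.extension_id("Labs - Culture Sensitivity"),
                    "operator_concept_id": ops,
                    "value_as_number":
                        sens_rows["dilution_value"].astype(float),
                    "value_as_concept_id":
                        sens_rows["interpretation"].map(interp).fillna(0),
                    "unit_concept_id": 0, "unit_source_value": None,
                    "visit_occurrence_id":
                        sens_rows["hadm_id"].map(self.visit_of),
                    "measurement_source_value": sens_rows["ab_name"],
                    "measurement_source_concept_id":
                        sens_rows["ab_itemid"].map(org_local).fillna(0),
                    "value_source_value": sens_rows["interpretation"],
                    "_src_table": "microbiologyevents",
                    "_src_row": sens_rows["row_id"].astype("int64"),
                    "_route": "MEASUREMENT", "_is_lab": False,
                    "_micro_fluid": sens_rows["spec_type_desc"],
                    "_micro_key": sens_rows["hadm_id"].astype(str) + "|"
                        + sens_rows["spec_itemid"].astype(str) + "|"
                        + sens_rows["org_itemid"].astype(str) + "|"
                        + sens_rows["charttime"].astype(str),
                    "_micro_role": "susceptibility"}))

        if not frames:
            self.out["measurement"] = empty_table(CDM_TABLES["measurement"])
            return
        all_rows = pd.concat(frames, ignore_index=True)
        all_rows["visit_detail_id"] = pd.NA
        ids = self.seq.take(len(all_rows))
        all_rows.insert(0, "measurement_id", ids)
        for table in all_rows["_src_table"].unique():
            part = all_rows[all_rows["_src_table"] == table]
            self.link(table, part["_src_row"], "measurement",
                      part["measurement_id"])
        # remember micro groupings for fact relationships
        if "_micro_key" in all_rows.columns:
            micro = all_rows[all_rows["_micro_key"].notna()]
            for _key, grp in micro.groupby("_micro_key"):
                orgs = grp[grp["_micro_role"] == "organism"]["measurement_id"]
                sens = grp[grp["_micro_role"] == "susceptibility"][
                    "measurement_id"]
                for org_id in orgs:
                    self._micro_groups.append(
                        (int(org_id), [int(s) for s in sens]))
        self._measurement_staging = all_rows
        keep = [c for c in CDM_TABLES["measurement"]]
        self.out["measurement"] = all_rows[keep].copy()

    def etl_specimen(self) -> None:
        """One specimen row per laboratory/microbiology measurement."""
        staged = getattr(self, "_measurement_staging", None)
        if staged is None or not len(staged):
            self.out["specimen"] = empty_table(CDM_TABLES["specimen"])
            return
        manual = self.vocab.manual_entries()
        fluid_concepts = {k[1]: v[0] for k, v in manual.items()
                          if k[0] == "lab_fluid"}
        is_lab = staged["_is_lab"].fillna(False).astype(bool)
        is_micro = staged.get("_micro_key")
        is_micro = is_micro.notna() if is_micro is not None else \
            pd.Series(False, index=staged.index)
        pool = staged[is_lab | is_micro]
        if not len(pool):
            self.out["specimen"] = empty_table(CDM_TABLES["specimen"])
            return
        fluid = pool.get("_specimen_fluid",
                         pd.Series(None, index=pool.index))
        if "_micro_fluid" in pool.columns:
            micro_fluid = pool["_micro_fluid"].map(
                lambda s: "Blood" if isinstance(s, str) and "BLOOD" in s
                else ("Urine" if isinstance(s, str) and "URINE" in s
                      else None))
            fluid = fluid.fillna(micro_fluid)
        ids = self.seq.take(len(pool))
        self.out["specimen"] = pd.DataFrame({
            "specimen_id": ids,
            "person_id": pool["person_id"],
            "specimen_concept_id": fluid.map(fluid_concepts).fillna(0),
            "specimen_type_concept_id": EHR_TYPE,
            "specimen_datetime": pool["measurement_datetime"],
            "specimen_source_value": fluid,
            "measurement_id": pool["measurement_id"]})
        for table in pool["_src_table"].unique():
            part = pool["_src_table"] == table
            self.link(table, pool.loc[part, "_src_row"], "specimen",
                      ids[np.asarray(part)])

    # -- drugs -------------------------------------------------------------

    def etl_drug_exposure(self) -> None:
        frames = []
        rx = self._kept["prescriptions"]
        if len(rx):
            rx_dec = self._std_map("prescriptions")
            code_of = {}
            for drug, _gen, ndc, _route in dd.FORMULARY:
                code_of[drug] = str(ndc) if ndc else drug
            std = rx["drug"].map(
                lambda d: rx_dec[code_of[d]].standard_concept_id
                if d in code_of and code_of[d] in rx_dec else 0)
            local = rx["drug"].map(
                lambda d: rx_dec[code_of[d]].local_concept_id
                if d in code_of and code_of[d] in rx_dec else 0)
            missing_end = rx["enddate"].isna()
            self.report.note("imputed_end", int(missing_end.sum()))
            end = rx["enddate"].where(~missing_end, rx["startdate"])
            frames.append(pd.DataFrame({
                "person_id": rx["subject_id"].map(self.person_of),
                "drug_concept_id": std,
                "drug_exposure_start_datetime": rx["startdate"],
                "drug_exposure_end_datetime": end,
                "drug_type_concept_id": RX_TYPE,
                "quantity": pd.to_numeric(rx["dose_val_rx"],
                                          errors="coerce"),
                "route_source_value": rx["route"],
                "visit_occurrence_id": rx["hadm_id"].map(self.visit_of),
                "drug_source_value": rx["drug"],
                "drug_source_concept_id": local,
                "dose_unit_source_value": rx["dose_unit_rx"],
                "_src_table": "prescriptions",
                "_src_row": rx["row_id"].astype("int64"),
                "_orderid": -1}))
        decisions = self._std_map("d_items")
        for table, start_col, end_col in (
                ("inputevents_cv", "charttime", "charttime"),
                ("inputevents_mv", "starttime", "endtime")):
            ev = self._kept[table]
            if not len(ev):
                continue
            std = ev["itemid"].map(
                {int(c): d.standard_concept_id for c, d in decisions.items()})
            local = ev["itemid"].map(
                {int(c): d.local_concept_id for c, d in decisions.items()})
            label = ev["itemid"].map(
                self.src["d_items"].set_index("itemid")["label"])
            frames.append(pd.DataFrame({
                "person_id": ev["subject_id"].map(self.person_of),
                "drug_concept_id": std.fillna(0),
                "drug_exposure_start_datetime": ev[start_col],
                "drug_exposure_end_datetime": ev[end_col],
                "drug_type_concept_id": EHR_TYPE,
                "quantity": ev["amount"].astype(float),
                "route_source_value": "IV",
                "visit_occurrence_id": ev["hadm_id"].map(self.visit_of),
                "drug_source_value": label,
                "drug_source_concept_id": local.fillna(0),
                "dose_unit_source_value": ev["amountuom"],
                "_src_table": table,
                "_src_row": ev["row_id"].astype("int64"),
                "_orderid": ev["orderid"].fillna(-1).astype("int64")
                if table == "inputevents_mv" else -1}))
        if not frames:
            self.out["drug_exposure"] = empty_table(
                CDM_TABLES["drug_exposure"])
            return
        all_rows = pd.concat(frames, ignore_index=True)
        ids = self.seq.take(len(all_rows))
        all_rows.insert(0, "drug_exposure_id", ids)
        for table in all_rows["_src_table"].unique():
            part = all_rows[all_rows["_src_table"] == table]
            self.link(table, part["_src_row"], "drug_exposure",
                      part["drug_exposure_id"])
        mv = all_rows[(all_rows["_src_table"] == "inputevents_mv")
                      & (all_rows["_orderid"] >= 0)]
        self._mv_solution = mv
        self.out["drug_exposure"] = all_rows[
            list(CDM_TABLES["drug_exposure"])].copy()

    # -- conditions, procedures, observations ------------------------------

    def etl_condition_occurrence(self) -> None:
        rows = []
        dx_prov: list[tuple[int, int]] = []
        adm_prov: list[tuple[int, int]] = []
        dec = self._std_map("d_icd_diagnoses")
        adm_time = self._kept["admissions"].set_index("hadm_id")[
            ["admittime", "dischtime"]]
        for row in self._kept["diagnoses_icd"].itertuples(index=False):
            d = dec.get(str(row.icd9_code))
            targets = list(d.all_targets) if d and d.all_targets else [0]
            hadm = int(row.hadm_id)
            when = adm_time.loc[hadm]
            for target in targets:
                cid = self.seq.allocate()
                rows.append(dict(
                    condition_occurrence_id=cid,
                    person_id=self.person_of[int(row.subject_id)],
                    condition_concept_id=target,
                    condition_start_datetime=when["admittime"],
                    condition_end_datetime=when["dischtime"],
                    condition_type_concept_id=EHR_TYPE,
                    visit_occurrence_id=self.visit_of[hadm],
                    condition_source_value=str(row.icd9_code),
                    condition_source_concept_id=d.local_concept_id
                    if d else 0))
                dx_prov.append((int(row.row_id), cid))
        # preliminary free-text admission diagnosis, kept local
        for row in self._kept["admissions"].itertuples(index=False):
            if not row.diagnosis:
                continue
            cid = self.seq.allocate()
            rows.append(dict(
                condition_occurrence_id=cid,
                person_id=self.person_of[int(row.subject_id)],
                condition_concept_id=0,
                condition_start_datetime=row.admittime,
                condition_end_datetime=row.dischtime,
                condition_type_concept_id=EHR_TYPE,
                visit_occurrence_id=self.visit_of[int(row.hadm_id)],
                condition_source_value=row.diagnosis,
                condition_source_concept_id=0))
            adm_prov.append((int(row.row_id), cid))
        self.out["condition_occurrence"] = pd.DataFrame(rows)
        if dx_prov:
            src, cdm = zip(*dx_prov)
            self.link("diagnoses_icd", src, "condition_occurrence", cdm)
        if adm_prov:
            src, cdm = zip(*adm_prov)
            self.link("admissions", src, "condition_occurrence", cdm)

    def etl_procedure_occurrence(self) -> None:
        rows = []
        prov: list[tuple[str, int, int]] = []
        adm_time = self._kept["admissions"].set_index("hadm_id")["admittime"]
        proc_dec = self._std_map("d_icd_procedures")
        for row in self._kept["procedures_icd"].itertuples(index=False):
            d = proc_dec.get(str(row.icd9_code))
            pid = self.seq.allocate()
            rows.append(dict(
                procedure_occurrence_id=pid,
                person_id=self.person_of[int(row.subject_id)],
                procedure_concept_id=d.standard_concept_id if d else 0,
                procedure_datetime=adm_time.loc[int(row.hadm_id)],
                procedure_end_datetime=None,
                procedure_type_concept_id=EHR_TYPE, quantity=1.0,
                visit_occurrence_id=self.visit_of[int(row.hadm_id)],
                procedure_source_value=str(row.icd9_code),
                procedure_source_concept_id=d.local_concept_id if d else 0))
            prov.append(("procedures_icd", int(row.row_id), pid))
        cpt_dec = self._std_map("cptevents")
        for row in self._kept["cptevents"].itertuples(index=False):
            d = cpt_dec.get(str(row.cpt_cd))
            pid = self.seq.allocate()
            rows.append(dict(
                procedure_occurrence_id=pid,
                person_id=self.person_of[int(row.subject_id)],
                procedure_concept_id=d.standard_concept_id if d else 0,
                procedure_datetime=row.chartdate,
                procedure_end_datetime=None,
                procedure_type_concept_id=EHR_TYPE, quantity=1.0,
                visit_occurrence_id=self.visit_of[int(row.hadm_id)],
                procedure_source_value=str(row.cpt_cd),
                procedure_source_concept_id=d.local_concept_id if d else 0))
            prov.append(("cptevents", int(row.row_id), pid))
        item_dec = self._std_map("d_items")
        for row in self._kept["procedureevents_mv"].itertuples(index=False):
            d = item_dec.get(str(row.itemid))
            pid = self.seq.allocate()
            rows.append(dict(
                procedure_occurrence_id=pid,
                person_id=self.person_of[int(row.subject_id)],
                procedure_concept_id=d.standard_concept_id if d else 0,
                procedure_datetime=row.starttime,
                procedure_end_datetime=row.endtime,
                procedure_type_concept_id=EHR_TYPE,
                quantity=float(row.value) if pd.notna(row.value) else 1.0,
                visit_occurrence_id=self.visit_of[int(row.hadm_id)],
                procedure_source_value=str(row.itemid),
                procedure_source_concept_id=d.local_concept_id if d else 0))
            prov.append(("procedureevents_mv", int(row.row_id), pid))
        self.out["procedure_occurrence"] = pd.DataFrame(rows)
        for table in ("procedures_icd", "cptevents", "procedureevents_mv"):
            part = [(r, c) for t, r, c in prov if t == table]
            if part:
                src, cdm = zip(*part)
                self.link(table, src, "procedure_occurrence", cdm)

    def etl_observation(self) -> None:
        frames = list(self._obs_buffers)
        adms = self._kept["admissions"]
        if len(adms):
            frames.append(pd.DataFrame({
                "person_id": adms["subject_id"].map(self.person_of),
                "observation_concept_id": 0,
                "observation_datetime": adms["admittime"],
                "observation_type_concept_id": EHR_TYPE,
                "value_as_number": np.nan,
                "value_as_string": adms["marital_status"],
                "value_as_concept_id": 0,
                "visit_occurrence_id": adms["hadm_id"].map(self.visit_of),
                "observation_source_value": "marital_status",
                "observation_source_concept_id": 0,
                "_src_table": "admissions",
                "_src_row": adms["row_id"].astype("int64")}))
        drg = self._kept["drgcodes"]
        if len(drg):
            frames.append(pd.DataFrame({
                "person_id": drg["subject_id"].map(self.person_of),
                "observation_concept_id":
                    self.vocab.extension_id("Drg Code"),
                "observation_datetime":
                    drg["hadm_id"].map(
                        adms.set_index("hadm_id")["dischtime"]),
                "observation_type_concept_id": EHR_TYPE,
                "value_as_number": drg["drg_severity"].astype(float),
                "value_as_string": drg["drg_code"],
                "value_as_concept_id": 0,
                "visit_occurrence_id": drg["hadm_id"].map(self.visit_of),
                "observation_source_value": drg["description"],
                "observation_source_concept_id": 0,
                "_src_table": "drgcodes",
                "_src_row": drg["row_id"].astype("int64")}))
        dte = self._kept["datetimeevents"]
        if len(dte):
            decisions = self._std_map("d_items")
            std = dte["itemid"].map(
                {int(c): d.standard_concept_id for c, d in decisions.items()})
            local = dte["itemid"].map(
                {int(c): d.local_concept_id for c, d in decisions.items()})
            frames.append(pd.DataFrame({
                "person_id": dte["subject_id"].map(self.person_of),
                "observation_concept_id": std.fillna(0),
                "observation_datetime": dte["charttime"],
                "observation_type_concept_id":
                    self.vocab.extension_id("Datetime Events"),
                "value_as_number": np.nan,
                "value_as_string": dte["value"].dt.strftime(
                    "%Y-%m-%d %H:%M:%S"),
                "value_as_concept_id": 0,
                "visit_occurrence_id": dte["hadm_id"].map(self.visit_of),
                "observation_source_value": dte["itemid"].map(
                    self.src["d_items"].set_index("itemid")["label"]),
                "observation_source_concept_id": local.fillna(0),
                "_src_table": "datetimeevents",
                "_src_row": dte["row_id"].astype("int64")}))
        if not frames:
            self.out["observation"] = empty_table(CDM_TABLES["observation"])
            return
        all_rows = pd.concat(frames, ignore_index=True)
        ids = self.seq.take(len(all_rows))
        all_rows.insert(0, "observation_id", ids)
        for table in all_rows["_src_table"].unique():
            part = all_rows[all_rows["_src_table"] == table]
            self.link(table, part["_src_row"], "observation",
                      part["observation_id"])
        self.out["observation"] = all_rows[
            list(CDM_TABLES["observation"])].copy()

    # -- notes, providers, callout ----------------------------------------

    def etl_note(self) -> None:
        ne = self._kept["noteevents"]
        if not len(ne):
            self.out["note"] = empty_table(CDM_TABLES["note"])
            return
        ids = self.seq.take(len(ne))
        when = ne["charttime"].fillna(ne["chartdate"])
        self.out["note"] = pd.DataFrame({
            "note_id": ids,
            "person_id": ne["subject_id"].map(self.person_of),
            "note_datetime": when,
            "note_type_concept_id": EHR_TYPE,
            "note_class_concept_id": 0,
            "note_title": ne["category"],
            "note_text": ne["text"],
            "encoding_concept_id": 0, "language_concept_id": 0,
            "provider_id": None,
            "visit_occurrence_id": ne["hadm_id"].map(self.visit_of),
            "note_source_value": ne["category"]})
        self.link("noteevents", ne["row_id"], "note", ids)

    def etl_provider(self) -> None:
        cg = self._kept["caregivers"]
        if not len(cg):
            self.out["provider"] = empty_table(CDM_TABLES["provider"])
            return
        ids = self.seq.take(len(cg))
        self.out["provider"] = pd.DataFrame({
            "provider_id": ids,
            "provider_name": cg["label"],
            "specialty_concept_id": 0,
            "specialty_source_value": cg["description"],
            "provider_source_value": cg["cgid"].astype(str)})
        self.link("caregivers", cg["row_id"], "provider", ids)

    def etl_cohort_attribute(self) -> None:
        co = self._kept["callout"]
        if not len(co):
            self.out["cohort_attribute"] = empty_table(
                CDM_TABLES["cohort_attribute"])
            return
        attr = self.vocab.extension_id("Callout Request")
        self.out["cohort_attribute"] = pd.DataFrame({
            "cohort_definition_id": attr,
            "subject_id": co["subject_id"].map(self.person_of),
            "cohort_start_date": co["createtime"],
            "cohort_end_date": co["outcometime"],
            "attribute_definition_id": attr,
            "value_as_number": co["request_tele"].astype(float),
            "value_as_concept_id": 0})
        # cohort_attribute has no sequence key; link rows by position
        self.link("callout", co["row_id"], "cohort_attribute",
                  np.arange(len(co)))

    # -- relationships -----------------------------------------------------

    def etl_fact_relationships(self) -> None:
        rows = []
        has_sens = self.vocab.extension_id("Has susceptibility test")
        sens_of = self.vocab.extension_id("Susceptibility test of")
        for org_id, sens_ids in self._micro_groups:
            for sid in sens_ids:
                rows.append((DOMAIN_MEASUREMENT, org_id,
                             DOMAIN_MEASUREMENT, sid, has_sens))
                rows.append((DOMAIN_MEASUREMENT, sid,
                             DOMAIN_MEASUREMENT, org_id, sens_of))
        drug_in = self.vocab.extension_id("Drug in solution")
        sol_has = self.vocab.extension_id("Solution contains drug")
        mv = self._mv_solution
        if mv is not None and len(mv):
            for _oid, grp in mv.groupby("_orderid"):
                if len(grp) < 2:
                    continue
                ids = grp["drug_exposure_id"].tolist()
                drug_id, sol_ids = ids[0], ids[1:]
                for sid in sol_ids:
                    rows.append((DOMAIN_DRUG, drug_id, DOMAIN_DRUG, sid,
                                 drug_in))
                    rows.append((DOMAIN_DRUG, sid, DOMAIN_DRUG, drug_id,
                                 sol_has))
        located = self.vocab.extension_id("Located at care site")
        site_of = self.vocab.extension_id("Care site of visit detail")
        vd = self.out.get("visit_detail")
        if vd is not None and len(vd):
            with_site = vd[vd["care_site_id"].notna()]
            for did, csid in zip(with_site["visit_detail_id"],
                                 with_site["care_site_id"]):
                rows.append((DOMAIN_VISIT_DETAIL, int(did),
                             DOMAIN_CARE_SITE, int(csid), located))
                rows.append((DOMAIN_CARE_SITE, int(csid),
                             DOMAIN_VISIT_DETAIL, int(did), site_of))
        self.out["fact_relationship"] = pd.DataFrame(
            rows, columns=["domain_concept_id_1", "fact_id_1",
                           "domain_concept_id_2", "fact_id_2",
                           "relationship_concept_id"])

    # -- finalize ----------------------------------------------------------

    def finalize(self) -> EtlResult:
        self.out["concept"] = self.vocab.concept_frame()
        self.out["concept_relationship"] = self.vocab.relationship_frame()
        cdm = CdmDatabase(self.out)
        prov = (pd.concat(self._prov, ignore_index=True) if self._prov
                else pd.DataFrame(columns=["source_table", "source_row_id",
                                           "cdm_table", "cdm_row_id"]))
        for name in SOURCE_TABLES:
            linked = prov.loc[prov["source_table"] == name,
                              "source_row_id"].nunique()
            self.report.linked_rows[name] = int(linked)
        for name, df in cdm.tables.items():
            self.report.target_rows[name] = len(df)
        violations = cdm.integrity_violations()
        if violations:
            raise EtlIntegrityError("; ".join(violations[:10]))
        return EtlResult(cdm=cdm, report=self.report, provenance=prov)


def run_etl(source: SourceDatabase, vocab: VocabularyStore | None = None,
            config=None) -> EtlResult:
    """Run the full transformation over a source bundle.

    The vocabulary store is cloned so repeated runs are independent and a
    fixed source yields an identical CDM every time.
    """
    import copy
    vocab = copy.deepcopy(vocab) if vocab is not None \
        else VocabularyStore.fixture()
    source.validate()
    etl = _Etl(source, vocab)
    etl.align_dictionaries()
    etl.filter_sources()
    etl.etl_person()
    etl.etl_visit_occurrence()
    etl.etl_visit_detail()
    etl.etl_measurement()
    etl.etl_specimen()
    etl.etl_drug_exposure()
    etl.etl_condition_occurrence()
    etl.etl_procedure_occurrence()
    etl.etl_observation()
    etl.etl_note()
    etl.etl_provider()
    etl.etl_cohort_attribute()
    etl.etl_fact_relationships()
    result = etl.finalize()
    result.decisions = etl.decision_frame()  # type: ignore[attr-defined]
    return result


def report_to_json(report: TransformReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2,
                                     sort_keys=True))
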
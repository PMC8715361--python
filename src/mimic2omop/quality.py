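"""Quality evaluation of one transformation run.

Four instruments, mirroring the evaluation discipline of the source
transformation project:

* **loss accounting** — percentage of rows and of columns lost per source
  table, the row side from the transform report, the column side from the
  committed declarative mapping specification;
* **characterization** — population-level baseline statistics computed
  identically over a source bundle or a CDM, for side-by-side comparison;
* **mapping coverage** — per CDM table, how many records and how many
  distinct source concepts carry a non-zero standard concept;
* **plausibility (Heel-style) checks** — a fixed list of data-quality rules
  with error/warning/notification severities.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import dictionaries as dd
from .etl import (CdmDatabase, TransformReport, DOMAIN_MEASUREMENT,
                  DOMAIN_VISIT_DETAIL, DOMAIN_CARE_SITE, DOMAIN_DRUG)
from .source import SourceDatabase
from .config import AGE_BANDS

OBFUSCATED_AGE_THRESHOLD = 150.0  # years; de-identification artifact


def _round_half_up(x: float, digits: int = 0) -> float:
    factor = 10 ** digits
    return math.floor(x * factor + 0.5) / factor


def load_mapping_spec() -> pd.DataFrame:
    path = Path(str(resources.files("mimic2omop").joinpath("data"))) \
        / "mapping_spec.csv"
    return pd.read_csv(path, keep_default_na=False)


# ---------------------------------------------------------------------------
# Loss accounting
# ---------------------------------------------------------------------------

def compute_loss(report: TransformReport,
                 mapping_spec: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows-lost and columns-lost percentages per source table.

    Row loss comes from the transform report (dropped / input); column loss
    from the mapping specification (columns with status ``dropped`` over all
    columns; ``consumed`` steering columns are not counted as lost).
    """
    spec = mapping_spec if mapping_spec is not None else load_mapping_spec()
    rows = []
    for table in sorted(report.input_rows):
        spec_t = spec[spec["source_table"] == table]
        if not len(spec_t):
            raise ValueError(f"mapping spec has no entry for table {table!r}")
        n_cols = len(spec_t)
        n_dropped_cols = int((spec_t["status"] == "dropped").sum())
        inp = report.input_rows[table]
        dropped = report.dropped_total(table)
        rows.append(dict(
            source_table=table,
            input_rows=inp,
            dropped_rows=dropped,
            rows_lost_pct=_round_half_up(100.0 * dropped / inp, 4)
            if inp else 0.0,
            total_columns=n_cols,
            dropped_columns=n_dropped_cols,
            columns_lost_pct=_round_half_up(100.0 * n_dropped_cols / n_cols),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Characterization
# ---------------------------------------------------------------------------

def age_years(when: pd.Series, dob: pd.Series) -> np.ndarray:
    """Age in years, safe for obfuscated (~300-year) birth dates.

    Computed from calendar components because a 300-year interval overflows
    the nanosecond-resolution timedelta.
    """
    when = pd.DatetimeIndex(when)
    dob = pd.DatetimeIndex(dob)
    return ((when.year - dob.year).to_numpy(dtype=float)
            + (when.dayofyear - dob.dayofyear).to_numpy(dtype=float)
            / 365.25)


def _quantiles(series: pd.Series) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between closest ranks."""
    s = series.dropna()
    if not len(s):
        return (float("nan"),) * 3
    return (float(s.quantile(0.5)), float(s.quantile(0.25)),
            float(s.quantile(0.75)))


def _band_of(age_years: np.ndarray) -> np.ndarray:
    """Age band index per admission; obfuscated ages fall in the oldest."""
    edges = [6, 16, 26, 46, 66, 81]
    idx = np.searchsorted(edges, age_years, side="right")
    return idx  # 0..6


@dataclass
class Characterization:
    items: dict[str, float | int | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.items)


def _characterize_source(db: SourceDatabase) -> Characterization:
    t = db.tables
    pats, adms = t["patients"], t["admissions"]
    c: dict = {}
    c["persons"] = len(pats)
    c["admissions"] = len(adms)
    c["icu_stays"] = len(t["icustays"])
    female = int((pats["gender"] == "F").sum())
    c["female_n"] = female
    c["female_pct"] = _round_half_up(100.0 * female / len(pats), 2) \
        if len(pats) else None
    if len(adms):
        merged = adms.merge(pats[["subject_id", "dob"]], on="subject_id")
        age = age_years(merged["admittime"], merged["dob"])
        obf = age > OBFUSCATED_AGE_THRESHOLD
        c["obfuscated_age_n"] = int(obf.sum())
        c["mean_age_years"] = _round_half_up(float(age[~obf].mean()), 2) \
            if (~obf).any() else None
        bands = _band_of(age)
        for i, name in enumerate(AGE_BANDS):
            c[f"age_band_{name}_n"] = int((bands == i).sum())
        c["emergency_n"] = int((adms["admission_type"] == "EMERGENCY").sum())
        c["elective_n"] = int((adms["admission_type"] == "ELECTIVE").sum())
        svc = t["services"]
        surgical = svc[svc["curr_service"].isin(dd.SURGICAL_SERVICES)]
        c["surgical_n"] = int(surgical["hadm_id"].nunique())
        los = (adms["dischtime"] - adms["admittime"]).dt.total_seconds() \
            / 86400.0
        m, q1, q3 = _quantiles(los)
        c["hospital_los_median_days"], c["hospital_los_q1"], \
            c["hospital_los_q3"] = (_round_half_up(m, 2),
                                    _round_half_up(q1, 2),
                                    _round_half_up(q3, 2))
        icu = t["icustays"]
        m, q1, q3 = _quantiles(icu["los"]) if len(icu) else (np.nan,) * 3
        c["icu_los_median_days"] = _round_half_up(m, 2) \
            if not math.isnan(m) else None
        hosp_deaths = int((adms["hospital_expire_flag"] == 1).sum())
        c["hospital_mortality_n"] = hosp_deaths
        c["hospital_mortality_pct"] = _round_half_up(
            100.0 * hosp_deaths / len(adms), 2)
        # ICU mortality: death timestamp falls inside an ICU stay interval
        icu_deaths = 0
        if len(icu):
            dead = pats[pats["dod"].notna()][["subject_id", "dod"]]
            j = icu.merge(dead, on="subject_id")
            icu_deaths = int(((j["dod"] >= j["intime"])
                              & (j["dod"] <= j["outtime"])).sum())
        c["icu_mortality_n"] = icu_deaths
        n_adm = len(adms)
        c["labs_per_admission"] = _round_half_up(len(t["labevents"]) / n_adm, 2)
        c["procedures_per_admission"] = _round_half_up(
            (len(t["procedures_icd"]) + len(t["cptevents"])
             + len(t["procedureevents_mv"])) / n_adm, 2)
        c["drugs_per_admission"] = _round_half_up(
            (len(t["prescriptions"]) + len(t["inputevents_cv"])
             + len(t["inputevents_mv"])) / n_adm, 2)
        c["diagnoses_per_admission"] = _round_half_up(
            len(t["diagnoses_icd"]) / n_adm, 2)
    return Characterization(c)


def _characterize_cdm(cdm: CdmDatabase) -> Characterization:
    from .derive import ICU_VISIT_DETAIL_CONCEPT
    t = cdm.tables
    person, vo = t["person"], t["visit_occurrence"]
    vd = t["visit_detail"]
    icu = vd[vd["visit_detail_concept_id"] == ICU_VISIT_DETAIL_CONCEPT]
    c: dict = {}
    c["persons"] = len(person)
    c["admissions"] = len(vo)
    c["icu_stays"] = len(icu)
    female = int((person["gender_concept_id"] == 8532).sum())
    c["female_n"] = female
    c["female_pct"] = _round_half_up(100.0 * female / len(person), 2) \
        if len(person) else None
    if len(vo):
        merged = vo.merge(person[["person_id", "birth_datetime"]],
                          on="person_id")
        # age at hospital admission: emergency visits start at ED
        # registration, which is within hours of admission
        age = age_years(merged["visit_start_datetime"],
                        merged["birth_datetime"])
        obf = age > OBFUSCATED_AGE_THRESHOLD
        c["obfuscated_age_n"] = int(obf.sum())
        c["mean_age_years"] = _round_half_up(float(age[~obf].mean()), 2) \
            if (~obf).any() else None
        bands = _band_of(age)
        for i, name in enumerate(AGE_BANDS):
            c[f"age_band_{name}_n"] = int((bands == i).sum())
        src = vo["visit_source_value"].fillna("")
        c["emergency_n"] = int(src.str.startswith("EMERGENCY").sum())
        c["elective_n"] = int(src.str.startswith("ELECTIVE").sum())
        c["surgical_n"] = int(src.str.split("/").str[-1]
                              .isin(dd.SURGICAL_SERVICES).sum())
        los = (vo["visit_end_datetime"]
               - vo["visit_start_datetime"]).dt.total_seconds() / 86400.0
        m, q1, q3 = _quantiles(los)
        c["hospital_los_median_days"], c["hospital_los_q1"], \
            c["hospital_los_q3"] = (_round_half_up(m, 2),
                                    _round_half_up(q1, 2),
                                    _round_half_up(q3, 2))
        ilos = (icu["visit_detail_end_datetime"]
                - icu["visit_detail_start_datetime"]).dt.total_seconds() \
            / 86400.0
        m, _q1, _q3 = _quantiles(ilos) if len(icu) else (np.nan,) * 3
        c["icu_los_median_days"] = _round_half_up(m, 2) \
            if not math.isnan(m) else None
        death = t["death"]
        c["hospital_mortality_n"] = len(death)
        c["hospital_mortality_pct"] = _round_half_up(
            100.0 * len(death) / len(vo), 2)
        icu_deaths = 0
        if len(icu) and len(death):
            j = icu.merge(death[["person_id", "death_datetime"]],
                          on="person_id")
            icu_deaths = int(
                ((j["death_datetime"] >= j["visit_detail_start_datetime"])
                 & (j["death_datetime"]
                    <= j["visit_detail_end_datetime"])).sum())
        c["icu_mortality_n"] = icu_deaths
        meas = t["measurement"]
        lab_types = {2000000006, 2000000010}  # lab stream + chart-side labs
        n_adm = len(vo)
        c["labs_per_admission"] = _round_half_up(
            int(meas["measurement_type_concept_id"].isin(lab_types).sum())
            / n_adm, 2)
        c["procedures_per_admission"] = _round_half_up(
            len(t["procedure_occurrence"]) / n_adm, 2)
        c["drugs_per_admission"] = _round_half_up(
            len(t["drug_exposure"]) / n_adm, 2)
        dx = t["condition_occurrence"]
        c["diagnoses_per_admission"] = _round_half_up(
            int((dx["condition_source_concept_id"] != 0).sum()) / n_adm, 2)
    return Characterization(c)


def characterize(db: SourceDatabase | CdmDatabase) -> Characterization:
    """Baseline population characterization of either database form."""
    if isinstance(db, SourceDatabase):
        return _characterize_source(db)
    return _characterize_cdm(db)


#: items that must agree exactly between source and CDM characterizations
INVARIANT_ITEMS = ("persons", "admissions", "female_n", "female_pct",
                   "emergency_n", "elective_n", "surgical_n",
                   "obfuscated_age_n") + tuple(
                       f"age_band_{b}_n" for b in AGE_BANDS)

#: item -> (relative tolerance, rationale)
DEFAULT_TOLERANCES: dict[str, tuple[float, str]] = {
    "icu_stays": (math.inf, "segment model never merges 24h re-entries, so "
                            "CDM stays >= source stays by design"),
    "icu_mortality_n": (0.35, "stay windows differ between the merged and "
                              "segment models"),
    "hospital_mortality_n": (0.05, "death source precedence may differ"),
    "hospital_mortality_pct": (0.05, "death source precedence"),
    "mean_age_years": (0.02, "age measured at ED registration vs admission"),
    "hospital_los_median_days": (0.10, "visit interval includes ED time"),
    "hospital_los_q1": (0.10, "visit interval includes ED time"),
    "hospital_los_q3": (0.10, "visit interval includes ED time"),
    "icu_los_median_days": (0.50, "per-segment vs merged-stay intervals"),
    "labs_per_admission": (math.inf, "chart-side laboratory rows join the "
                                     "laboratory stream, so CDM >= source"),
    "procedures_per_admission": (0.05, "rewritten rows filtered"),
    "drugs_per_admission": (0.05, "rewritten rows filtered"),
    "diagnoses_per_admission": (0.60, "one-to-many standard mapping emits "
                                      "one row per target"),
}


def compare_characterizations(a: Characterization, b: Characterization,
                              tolerances: dict | None = None) -> pd.DataFrame:
    """Item-by-item diff; invariant items demand exact equality."""
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    rows = []
    for item in sorted(set(a.items) | set(b.items)):
        va, vb = a.items.get(item), b.items.get(item)
        if va is None or vb is None or (isinstance(va, float)
                                        and math.isnan(va)):
            status, rationale = "missing", ""
        elif item in INVARIANT_ITEMS:
            status = "equal" if va == vb else "violation"
            rationale = "invariant item: exact equality required"
        else:
            rel_tol, rationale = tol.get(item, (0.0, ""))
            if va == vb:
                status = "equal"
            elif item in ("icu_stays", "labs_per_admission") and vb >= va:
                status = "within_tolerance"
            elif item in ("icu_stays", "labs_per_admission"):
                status = "violation"
                rationale = "CDM value must not fall below source value"
            else:
                denom = max(abs(va), 1e-9)
                status = "within_tolerance" \
                    if abs(vb - va) / denom <= rel_tol else "violation"
        rows.append(dict(item=item, source=va, cdm=vb, status=status,
                         rationale=rationale))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mapping coverage
# ---------------------------------------------------------------------------

#: table -> (standard concept column, source concept column)
_COVERAGE_COLUMNS = {
    "person": ("gender_concept_id", "gender_source_value"),
    "visit_occurrence": ("visit_concept_id", "visit_source_value"),
    "visit_detail": ("visit_detail_concept_id", "visit_detail_concept_id"),
    "care_site": ("place_of_service_concept_id", "care_site_source_value"),
    "condition_occurrence": ("condition_concept_id",
                             "condition_source_value"),
    "drug_exposure": ("drug_concept_id", "drug_source_value"),
    "measurement": ("measurement_concept_id", "measurement_source_value"),
    "observation": ("observation_concept_id", "observation_source_value"),
    "procedure_occurrence": ("procedure_concept_id",
                             "procedure_source_value"),
    "specimen": ("specimen_concept_id", "specimen_source_value"),
    "note": ("note_type_concept_id", "note_source_value"),
}


def mapping_coverage(cdm: CdmDatabase) -> pd.DataFrame:
    """Records and distinct source concepts carrying a standard concept."""
    rows = []
    for table, (std_col, src_col) in _COVERAGE_COLUMNS.items():
        df = cdm.tables[table]
        n = len(df)
        mapped = int(((df[std_col].notna()) & (df[std_col] != 0)).sum())
        src = df[src_col].fillna("<null>")
        distinct = int(src.nunique())
        mapped_src = int(src[(df[std_col].notna())
                             & (df[std_col] != 0)].nunique())
        rows.append(dict(
            table=table.upper(), records_n=n, mapped_records_n=mapped,
            mapped_records_pct=_round_half_up(100.0 * mapped / n)
            if n else None,
            source_concepts_n=distinct, mapped_source_concepts_n=mapped_src,
            mapped_source_concepts_pct=_round_half_up(
                100.0 * mapped_src / distinct) if distinct else None))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plausibility (Heel-style) checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    check: str
    count: int
    severity: str  # error | warning | notification


def heel_checks(cdm: CdmDatabase,
                shift_window: tuple[int, int] = (2100, 2200)
                ) -> list[Finding]:
    """Run the committed plausibility check list over a CDM."""
    t = cdm.tables
    findings: list[Finding] = []

    def add(check: str, count: int, severity: str) -> None:
        if count:
            findings.append(Finding(check, int(count), severity))

    person = t["person"][["person_id", "birth_datetime"]]
    event_tables = {
        "measurement": "measurement_datetime",
        "observation": "observation_datetime",
        "condition_occurrence": "condition_start_datetime",
        "drug_exposure": "drug_exposure_start_datetime",
        "procedure_occurrence": "procedure_datetime",
    }
    before_birth = 0
    future = 0
    window_hi = pd.Timestamp(f"{shift_window[1]}-12-31")
    for table, col in event_tables.items():
        df = t[table][["person_id", col]].merge(person, on="person_id")
        before_birth += int((df[col] < df["birth_datetime"]).sum())
        future += int((t[table][col] > window_hi).sum())
    add("event_before_birth", before_birth, "error")
    add("event_beyond_shift_window", future, "notification")

    death = t["death"][["person_id", "death_datetime"]]
    after_death = 0
    if len(death):
        grace = pd.Timedelta(days=60)
        for table, col in event_tables.items():
            df = t[table][["person_id", col]].merge(death, on="person_id")
            after_death += int((df[col] > df["death_datetime"] + grace).sum())
    add("event_after_death_60d", after_death, "warning")

    vo = t["visit_occurrence"]
    if len(vo):
        merged = vo.merge(person, on="person_id")
        age = age_years(merged["visit_start_datetime"],
                        merged["birth_datetime"])
        add("age_over_150_obfuscated", int((age > 150).sum()),
            "notification")
        neg = (vo["visit_end_datetime"]
               < vo["visit_start_datetime"]).sum()
        add("negative_length_of_stay", int(neg), "error")

    vd = t["visit_detail"]
    if len(vd) and len(vo):
        j = vd.merge(vo[["visit_occurrence_id", "visit_start_datetime",
                         "visit_end_datetime"]], on="visit_occurrence_id")
        outside = ((j["visit_detail_start_datetime"]
                    < j["visit_start_datetime"])
                   | (j["visit_detail_end_datetime"]
                      > j["visit_end_datetime"]))
        add("visit_detail_outside_visit", int(outside.sum()), "error")

    persons = set(t["person"]["person_id"])
    orphan_meas = int((~t["measurement"]["person_id"].isin(persons)).sum())
    add("measurement_without_person", orphan_meas, "error")

    for table, key in (("person", "person_id"),
                       ("measurement", "measurement_id"),
                       ("visit_occurrence", "visit_occurrence_id"),
                       ("visit_detail", "visit_detail_id")):
        add(f"duplicate_primary_key_{table}",
            int(t[table][key].duplicated().sum()), "error")

    fr = t["fact_relationship"]
    if len(fr):
        pools = {DOMAIN_MEASUREMENT: set(t["measurement"]["measurement_id"]),
                 DOMAIN_VISIT_DETAIL: set(vd["visit_detail_id"]),
                 DOMAIN_CARE_SITE: set(t["care_site"]["care_site_id"]),
                 DOMAIN_DRUG: set(t["drug_exposure"]["drug_exposure_id"])}
        orphans = 0
        for side in (1, 2):
            dom = fr[f"domain_concept_id_{side}"]
            fid = fr[f"fact_id_{side}"]
            for d, pool in pools.items():
                orphans += int((~fid[dom == d].isin(pool)).sum())
        add("orphan_fact_relationship", orphans, "error")

    for table, (std_col, _src) in _COVERAGE_COLUMNS.items():
        df = t[table]
        if not len(df):
            continue
        unmapped = float((df[std_col].fillna(0) == 0).mean())
        if unmapped > 0.5:
            add(f"unmapped_rate_over_50pct_{table}", int(unmapped * 100),
                "notification")
    return findings


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    loss: pd.DataFrame
    characterization_source: Characterization | None
    characterization_cdm: Characterization
    comparison: pd.DataFrame | None
    coverage: pd.DataFrame
    findings: list[Finding]

    def severity_counts(self) -> dict[str, int]:
        out = {"error": 0, "warning": 0, "notification": 0}
        for f in self.findings:
            out[f.severity] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loss": self.loss.to_dict(orient="records"),
            "characterization_source":
                self.characterization_source.to_dict()
                if self.characterization_source else None,
            "characterization_cdm": self.characterization_cdm.to_dict(),
            "comparison": self.comparison.to_dict(orient="records")
            if self.comparison is not None else None,
            "coverage": self.coverage.to_dict(orient="records"),
            "findings": [f.__dict__ for f in self.findings],
            "severity_counts": self.severity_counts(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    def render_text(self) -> str:
        lines = ["== Data lost ==", self.loss.to_string(index=False), "",
                 "== Terminology mapping coverage ==",
                 self.coverage.to_string(index=False), ""]
        if self.comparison is not None:
            lines += ["== Characterization: source vs CDM ==",
                      self.comparison.to_string(index=False), ""]
        lines.append("== Plausibility findings ==")
        if self.findings:
            for f in self.findings:
                lines.append(f"  [{f.severity}] {f.check}: {f.count}")
        else:
            lines.append("  none")
        sc = self.severity_counts()
        lines.append(f"{sc['error']} errors, {sc['warning']} warnings, "
                     f"{sc['notification']} notifications")
        return "\n".join(lines)


def evaluate(result, source: SourceDatabase | None = None,
             shift_window: tuple[int, int] = (2100, 2200)) -> QualityReport:
    """Full quality evaluation of one ETL result."""
    loss = compute_loss(result.report)
    char_cdm = characterize(result.cdm)
    char_src = characterize(source) if source is not None else None
    comparison = compare_characterizations(char_src, char_cdm) \
        if char_src is not None else None
    return QualityReport(
        loss=loss, characterization_source=char_src,
        characterization_cdm=char_cdm, comparison=comparison,
        coverage=mapping_coverage(result.cdm),
        findings=heel_checks(result.cdm, shift_window))
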
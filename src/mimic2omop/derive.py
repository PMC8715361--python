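"""Clinical value parsing, normalization and derived quantities.

Covers the analyst-facing layer on top of the structural transformation:

* a total parser splitting textual laboratory values into operator, number
  and unit;
* unit normalization (body temperature to Celsius, pounds to kilograms);
* standard derived quantities: albumin-corrected calcium, pH-corrected
  potassium, the PaO2/FiO2 ratio and calculated serum osmolarity;
* SAPS II, the Simplified Acute Physiology Score, over worst first-24-hour
  ICU values, with its logistic in-hospital mortality equation;
* the denormalized and specialized analyst tables (microbiology antibiogram,
  ICU stays).

Formulas the severity score and corrections use are the standard published
clinical definitions; the point bands ship as a data table, not code.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

OPERATORS = ("=", "<", "≤", ">", "≥")

#: operator -> standard operator concept id
OPERATOR_CONCEPTS = {"=": 4172703, "<": 4171756, "≤": 4172704,
                     ">": 4172705, "≥": 4171754}

_ASCII_OPS = {"<=": "≤", ">=": "≥", "=<": "≤", "=>": "≥"}

_VALUE_RX = re.compile(
    r"^\s*(<=|>=|=<|=>|[<>=≤≥])?\s*"
    r"(\d+(?:\.\d+)?)\s*(.*?)\s*$")


@dataclass(frozen=True)
class ValueParse:
    """Decomposition of a textual result value."""

    operator: str = "="
    number: float | None = None
    unit: str | None = None
    residual: str = ""

    def reconstruct(self) -> str:
        """Whitespace-normalized reassembly of the parsed input."""
        parts = []
        if self.number is not None:
            if self.operator != "=":
                parts.append(self.operator)
            parts.append(f"{self.number:g}")
            if self.unit:
                parts.append(self.unit)
        if self.residual:
            parts.append(self.residual)
        return " ".join(" ".join(parts).split())


def parse_lab_value(text: str | None) -> ValueParse:
    """Split a textual lab value into operator, number, unit and residual.

    Total over all inputs: anything that does not start with an optional
    comparator followed by a decimal number is returned untouched in
    ``residual`` with the identity operator.
    """
    if text is None:
        return ValueParse()
    m = _VALUE_RX.match(text)
    if not m or m.group(2) is None:
        return ValueParse(residual=" ".join(str(text).split()))
    op = m.group(1) or "="
    op = _ASCII_OPS.get(op, op)
    unit = " ".join(m.group(3).split()) or None
    return ValueParse(operator=op, number=float(m.group(2)), unit=unit)


class UnitError(ValueError):
    """Unknown or unusable measurement unit."""


def normalize_temperature(value: float, unit: str) -> float:
    """Convert a body temperature to Celsius (Fahrenheit rounded to 0.1)."""
    u = unit.strip().upper().replace("DEG.", "").replace("DEG", "").strip()
    u = u.lstrip("°")
    if u in ("C", "CELSIUS"):
        return float(value)
    if u in ("F", "FAHRENHEIT"):
        return round((float(value) - 32.0) * 5.0 / 9.0, 1)
    raise UnitError(f"unknown temperature unit {unit!r}")


LB_TO_KG = 0.453592
IN_TO_CM = 2.54


def corrected_calcium(total_calcium: float, albumin: float) -> float:
    """Albumin-corrected serum calcium (mg/dL), reference albumin 4 g/dL."""
    if total_calcium <= 0 or albumin <= 0:
        raise ValueError("calcium and albumin must be positive")
    return round(total_calcium + 0.8 * (4.0 - albumin), 2)


def corrected_potassium(potassium: float, ph: float) -> float:
    """pH-corrected serum potassium (mEq/L): 0.6 mEq/L per 0.1 pH unit."""
    if not (6.5 <= ph <= 8.0):
        raise ValueError(f"pH {ph} outside plausible range [6.5, 8.0]")
    return round(potassium + 6.0 * (ph - 7.4), 2)


def pf_ratio(pao2: float, fio2: float) -> float:
    """PaO2/FiO2 ratio; FiO2 recorded in percent (>1) is coerced to fraction."""
    if fio2 > 1.0:
        fio2 = fio2 / 100.0
    if fio2 <= 0:
        raise ValueError(f"FiO2 must be positive, got {fio2}")
    return round(pao2 / fio2, 2)


def calculated_osmolarity(sodium: float, glucose: float,
                          urea_nitrogen: float) -> float:
    """Calculated serum osmolarity (mOsm/L): 2 Na + glucose/18 + BUN/2.8."""
    if sodium < 0 or glucose < 0 or urea_nitrogen < 0:
        raise ValueError("osmolarity inputs must be non-negative")
    return round(2.0 * sodium + glucose / 18.0 + urea_nitrogen / 2.8, 2)


# ---------------------------------------------------------------------------
# SAPS II
# ---------------------------------------------------------------------------

CHRONIC_CATEGORIES = ("none", "metastatic_cancer", "hematologic_malignancy",
                      "aids")
CHRONIC_POINTS = {"none": 0, "metastatic_cancer": 9,
                  "hematologic_malignancy": 10, "aids": 17}
ADMISSION_CATEGORIES = ("scheduled_surgical", "medical",
                        "unscheduled_surgical")
ADMISSION_POINTS = {"scheduled_surgical": 0, "medical": 6,
                    "unscheduled_surgical": 8}

_MORTALITY_COEFFS = (-7.7631, 0.0737, 0.9971)


def _load_point_table() -> dict[str, list[tuple[float, float, int]]]:
    path = Path(str(resources.files("mimic2omop").joinpath("data"))) \
        / "saps2_points.csv"
    table: dict[str, list[tuple[float, float, int]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lo = float(row["lower"])
            hi = float(row["upper"]) if row["upper"] else math.inf
            table.setdefault(row["component"], []).append(
                (lo, hi, int(row["points"])))
    return table


_POINT_TABLE = _load_point_table()


def band_points(component: str, value: float) -> int:
    """Points for one physiologic component from the committed band table."""
    for lo, hi, pts in _POINT_TABLE[component]:
        if lo <= value < hi:
            return pts
    raise ValueError(f"{component} value {value} outside scored bands")


@dataclass(frozen=True)
class Saps2Input:
    """Worst-first-24-ICU-hour values for one stay; None scores 0 points."""

    age: float
    heart_rate: float | None = None
    systolic_bp: float | None = None
    temperature: float | None = None
    pf_ratio: float | None = None       # scored only when ventilated
    ventilated: bool = False
    urine_output: float | None = None   # L per 24 h
    bun: float | None = None            # serum urea nitrogen, mg/dL
    wbc: float | None = None            # 10^3 per uL
    potassium: float | None = None
    sodium: float | None = None
    bicarbonate: float | None = None
    bilirubin: float | None = None
    gcs: float | None = None            # Glasgow coma scale, 3-15
    chronic: str = "none"
    admission: str = "medical"


@dataclass(frozen=True)
class Saps2Result:
    score: int
    mortality: float
    components: dict[str, int] = field(default_factory=dict, compare=False)
    missing: tuple[str, ...] = ()


def saps2_mortality(score: float) -> float:
    """In-hospital mortality probability for a SAPS II score."""
    b0, b1, b2 = _MORTALITY_COEFFS
    logit = b0 + b1 * score + b2 * math.log(score + 1.0)
    return 1.0 / (1.0 + math.exp(-logit))


def saps2(inp: Saps2Input) -> Saps2Result:
    """Score one stay and evaluate the mortality logit.

    Missing physiology components score 0 points (the convention for values
    never measured) and are reported in ``missing``.
    """
    if inp.gcs is not None and not (3 <= inp.gcs <= 15):
        raise ValueError(f"Glasgow score must be in [3, 15], got {inp.gcs}")
    if inp.chronic not in CHRONIC_POINTS:
        raise ValueError(f"unknown chronic disease category {inp.chronic!r}")
    if inp.admission not in ADMISSION_POINTS:
        raise ValueError(f"unknown admission category {inp.admission!r}")
    components: dict[str, int] = {}
    missing: list[str] = []
    components["age"] = band_points("age", inp.age)
    numeric = ("heart_rate", "systolic_bp", "temperature", "urine_output",
               "bun", "wbc", "potassium", "sodium", "bicarbonate",
               "bilirubin", "gcs")
    for name in numeric:
        value = getattr(inp, name)
        if value is None:
            components[name] = 0
            missing.append(name)
        else:
            components[name] = band_points(name, float(value))
    if inp.ventilated and inp.pf_ratio is not None:
        components["pf_ratio"] = band_points("pf_ratio", inp.pf_ratio)
    else:
        components["pf_ratio"] = 0
        if inp.ventilated:
            missing.append("pf_ratio")
    components["chronic"] = CHRONIC_POINTS[inp.chronic]
    components["admission"] = ADMISSION_POINTS[inp.admission]
    score = int(sum(components.values()))
    return Saps2Result(score=score, mortality=saps2_mortality(score),
                       components=components, missing=tuple(missing))


# ---------------------------------------------------------------------------
# Denormalized and specialized tables
# ---------------------------------------------------------------------------

def build_denormalized(cdm, vocab) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Attach ``*_concept_name`` columns beside every ``*_concept_id`` column.

    Row counts and original columns are untouched, so any query written
    against the normalized tables returns identical results.  Returns the
    denormalized tables and a list of warnings for dangling concept ids.
    """
    names = cdm.tables["concept"].set_index("concept_id")["concept_name"]
    warnings: list[str] = []
    out: dict[str, pd.DataFrame] = {}
    for table, df in cdm.tables.items():
        if table in ("concept", "concept_relationship", "fact_relationship"):
            continue
        if not any(c.endswith("_concept_id") for c in df.columns):
            continue
        denorm = df.copy()
        for col in [c for c in df.columns if c.endswith("_concept_id")]:
            mapped = df[col].map(names)
            dangling = df[col].notna() & (df[col] != 0) & mapped.isna()
            if dangling.any():
                warnings.append(
                    f"{table}.{col}: {int(dangling.sum())} dangling concept "
                    "ids")
                mapped = mapped.where(~dangling,
                                      "Unknown (" + df[col].astype(str) + ")")
            denorm[col.replace("_concept_id", "_concept_name")] = mapped
        out[table] = denorm
    return out, warnings


def build_microbiology_table(cdm) -> pd.DataFrame:
    """Flatten organism/susceptibility pairs into one antibiogram row each.

    One row per (organism measurement, susceptibility measurement) pair from
    the fact-relationship wiring; organisms without susceptibility testing
    are kept with absent antibiotic fields.
    """
    meas = cdm.tables["measurement"]
    names = cdm.tables["concept"].set_index("concept_id")["concept_name"]
    org_type = 2000000007
    sens_type = 2000000008
    organisms = meas[meas["measurement_type_concept_id"] == org_type]
    sens = meas[meas["measurement_type_concept_id"] == sens_type]
    fr = cdm.tables["fact_relationship"]
    links = fr[fr["fact_id_1"].isin(set(organisms["measurement_id"]))
               & fr["fact_id_2"].isin(set(sens["measurement_id"]))]
    merged = links.merge(
        organisms.add_prefix("org_"), left_on="fact_id_1",
        right_on="org_measurement_id")
    merged = merged.merge(sens.add_prefix("ab_"), left_on="fact_id_2",
                          right_on="ab_measurement_id")
    lonely = organisms[~organisms["measurement_id"].isin(links["fact_id_1"])]
    rows = pd.DataFrame({
        "person_id": merged["org_person_id"],
        "visit_occurrence_id": merged["org_visit_occurrence_id"],
        "measurement_datetime": merged["org_measurement_datetime"],
        "specimen_concept_id": merged["org_measurement_concept_id"],
        "specimen_source_value": merged["org_measurement_source_value"],
        "organism_concept_id": merged["org_value_as_concept_id"],
        "organism_source_value": merged["org_value_source_value"],
        "antibiotic_concept_id": merged["ab_measurement_concept_id"],
        "antibiotic_source_value": merged["ab_measurement_source_value"],
        "antibiotic_interpretation_concept_id": merged["ab_value_as_concept_id"],
        "organism_measurement_id": merged["org_measurement_id"],
        "antibiotic_measurement_id": merged["ab_measurement_id"],
    })
    if len(lonely):
        lone = pd.DataFrame({
            "person_id": lonely["person_id"],
            "visit_occurrence_id": lonely["visit_occurrence_id"],
            "measurement_datetime": lonely["measurement_datetime"],
            "specimen_concept_id": lonely["measurement_concept_id"],
            "specimen_source_value": lonely["measurement_source_value"],
            "organism_concept_id": lonely["value_as_concept_id"],
            "organism_source_value": lonely["value_source_value"],
            "organism_measurement_id": lonely["measurement_id"],
        })
        rows = pd.concat([rows, lone], ignore_index=True)
    rows["organism_concept_name"] = rows["organism_concept_id"].map(names)
    rows["antibiotic_interpretation_concept_name"] = \
        rows["antibiotic_interpretation_concept_id"].map(names)
    return rows.sort_values(
        ["organism_measurement_id", "antibiotic_measurement_id"],
        na_position="first").reset_index(drop=True)


def antibiogram_by_fact_relationship(cdm, organism_value_concept_id: int,
                                     specimen_measurement_concept_id: int
                                     ) -> set[str]:
    """Antibiotic susceptibility panel via the generic fact-relationship path.

    Selects measurements of the culture-sensitivity type linked through
    FACT_RELATIONSHIP to an organism measurement with the given identified
    organism and specimen-test concept.
    """
    meas = cdm.tables["measurement"]
    staph = meas[
        (meas["measurement_type_concept_id"] == 2000000007)
        & (meas["value_as_concept_id"] == organism_value_concept_id)
        & (meas["measurement_concept_id"] == specimen_measurement_concept_id)]
    fr = cdm.tables["fact_relationship"]
    linked = fr[fr["fact_id_1"].isin(set(staph["measurement_id"]))]
    sens = meas[(meas["measurement_id"].isin(set(linked["fact_id_2"])))
                & (meas["measurement_type_concept_id"] == 2000000008)]
    return set(sens["measurement_source_value"].dropna())


def antibiogram_by_denormalized(micro: pd.DataFrame,
                                organism_concept_id: int,
                                specimen_concept_id: int) -> set[str]:
    """The same antibiogram from the flattened microbiology table."""
    hit = micro[(micro["organism_concept_id"] == organism_concept_id)
                & (micro["specimen_concept_id"] == specimen_concept_id)]
    return set(hit["antibiotic_source_value"].dropna())


ICU_VISIT_DETAIL_CONCEPT = 32037


def build_icustays_table(cdm) -> pd.DataFrame:
    """One row per ICU-typed visit-detail segment with fractional-day LOS."""
    vd = cdm.tables["visit_detail"]
    icu = vd[vd["visit_detail_concept_id"] == ICU_VISIT_DETAIL_CONCEPT].copy()
    los = (icu["visit_detail_end_datetime"]
           - icu["visit_detail_start_datetime"]).dt.total_seconds() / 86400.0
    return pd.DataFrame({
        "visit_detail_id": icu["visit_detail_id"],
        "person_id": icu["person_id"],
        "visit_occurrence_id": icu["visit_occurrence_id"],
        "care_site_id": icu["care_site_id"],
        "icu_in_datetime": icu["visit_detail_start_datetime"],
        "icu_out_datetime": icu["visit_detail_end_datetime"],
        "los_days": los.round(4),
    }).reset_index(drop=True)
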
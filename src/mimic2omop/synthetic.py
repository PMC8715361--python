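"""Synthetic source-database generator.

Produces MIMIC-III-schema cohorts whose marginal statistics (gender split,
age bands, admission types, per-admission event rates) follow the generator
configuration, with the de-identification artifacts of the real data: all
timestamps date-shifted into a future window, dates of birth of patients
older than 89 moved so the computed age is about 300 years, and a neonatal
subpopulation filling the youngest age band.

The generator is a pure function of its configuration (including the seed):
the same config yields a bit-identical database.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dictionaries as dd
from .config import GeneratorConfig, AGE_BANDS
from .schemas import FLAG_DIALECT
from .source import SourceDatabase

DAY = 86400
SUBJECT_BASE = 10_000
HADM_BASE = 100_000
ICUSTAY_BASE = 200_000

#: (low, high] age in years per band; the 0-5 band is neonatal
_BAND_AGES = {"0-5": (0, 0), "6-15": (6, 15), "16-25": (16, 25),
              "26-45": (26, 45), "46-65": (46, 65), "66-80": (66, 80),
              ">80": (81, 99)}

# relative sampling weight of each chart item (temperature variants common)
_CHART_WEIGHTS = np.array([3, 1, 3, 1, 2, 1,      # temperatures
                           4, 3, 3, 2, 3, 2, 3, 2,  # hr/bp/rr/spo2
                           2, 1, 1, 1, 1,           # gcs/weight/height/tobacco
                           2, 2, 1], dtype=float)   # chart-side labs
_CHART_WEIGHTS /= _CHART_WEIGHTS.sum()

_LAB_WEIGHTS = np.array([2, 2, 2, 4, 4, 3, 4, 2, 2, 3, 3, 3, 2, 3, 3, 1, 1, 1],
                        dtype=float)
_LAB_WEIGHTS /= _LAB_WEIGHTS.sum()


def _sec(ts: pd.Timestamp) -> int:
    return int(ts.value // 10**9)


def _minute(sec):
    return np.asarray(sec, dtype="int64") // 60 * 60


class _ColumnBuffer:
    """Accumulates per-admission column arrays; concatenated once at the end."""

    def __init__(self):
        self.cols: dict[str, list] = {}

    def extend(self, **arrays):
        n = {len(np.atleast_1d(v)) for v in arrays.values()}
        assert len(n) == 1
        for k, v in arrays.items():
            self.cols.setdefault(k, []).append(np.atleast_1d(v))

    def frame(self) -> pd.DataFrame:
        if not self.cols:
            return pd.DataFrame()
        return pd.DataFrame({k: np.concatenate(v) for k, v in self.cols.items()})


def _note_text(rng: np.random.Generator, category: str) -> str:
    """Clinical note with section headers and extractable numeric entities."""
    lines = ["Admission note." if category != "Discharge summary"
             else "Discharge summary of hospital course."]
    weight_lb = round(float(rng.uniform(100, 280)), 0)
    height_in = round(float(rng.uniform(58, 76)), 0)
    bmi = round(float(rng.uniform(17, 42)), 1)
    ef = int(rng.integers(15, 76))
    sections = [
        ("Chief Complaint:", "Shortness of breath and fevers."),
        ("History of Present Illness:",
         "Patient presented with worsening symptoms over several days."),
        ("Past Medical History:", "Hypertension. Diabetes mellitus."),
        ("Medications:", "Aspirin, heparin, insulin sliding scale."),
        ("Physical Exam:",
         f"Wt: {weight_lb:.0f} lb Height: {height_in:.0f} in BMI: {bmi}"),
        ("Studies:", f"Echo with EF: {ef}%."),
        ("Assessment and Plan:", "Continue current management and monitor."),
    ]
    keep = rng.random(len(sections)) < 0.8
    keep[4] = True  # always carry the measurement line
    for (head, body), k in zip(sections, keep):
        if k:
            lines.append(head)
            lines.append(body)
    return "\n".join(lines)


def generate_source(config: GeneratorConfig) -> SourceDatabase:
    """Generate a complete synthetic source database from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tables: dict[str, list[dict]] = {
        name: [] for name in
        ("patients", "admissions", "transfers", "services", "icustays",
         "outputevents", "microbiologyevents", "inputevents_cv",
         "inputevents_mv", "procedureevents_mv", "procedures_icd",
         "cptevents", "noteevents", "datetimeevents", "drgcodes", "callout")}
    chart = _ColumnBuffer()
    labs = _ColumnBuffer()
    rx = _ColumnBuffer()
    dx = _ColumnBuffer()

    cgids = list(range(1000, 1020))
    n_bands = len(AGE_BANDS)
    lab_itemids = np.array([it[0] for it in dd.LAB_ITEMS])
    lab_lo = np.array([it[7][0] if it[6] == "numeric" else np.nan
                       for it in dd.LAB_ITEMS])
    lab_hi = np.array([it[7][1] if it[6] == "numeric" else np.nan
                       for it in dd.LAB_ITEMS])
    lab_kind = np.array([{"numeric": 0, "comparator": 1, "qualitative": 2}[it[6]]
                         for it in dd.LAB_ITEMS])
    lab_unit = np.array([it[5] or "" for it in dd.LAB_ITEMS], dtype=object)
    chart_itemids = np.array([it[0] for it in dd.CHART_ITEMS])
    chart_lo = np.array([it[5][0] if it[4] == "numeric" else np.nan
                         for it in dd.CHART_ITEMS])
    chart_hi = np.array([it[5][1] if it[4] == "numeric" else np.nan
                         for it in dd.CHART_ITEMS])
    chart_text = np.array([it[4] == "text" for it in dd.CHART_ITEMS])
    chart_unit = np.array([it[3] or "" for it in dd.CHART_ITEMS], dtype=object)
    icd9_codes = [c for c, _ in dd.ICD9_DIAGNOSES]

    hadm_counter = HADM_BASE
    icustay_counter = ICUSTAY_BASE
    orderid_counter = 500_000
    window_lo, window_hi = config.date_shift_window
    window_start = pd.Timestamp(f"{window_lo}-01-01")
    window_days = (pd.Timestamp(f"{window_hi}-01-01") - window_start).days - 800

    for p in range(config.n_patients):
        subject_id = SUBJECT_BASE + p
        female = rng.random() < config.female_fraction
        band = AGE_BANDS[int(rng.choice(n_bands, p=np.asarray(
            config.age_band_weights) / np.sum(config.age_band_weights)))]
        neonate = band == "0-5"
        lo, hi = _BAND_AGES[band]
        age = 0.0 if neonate else float(rng.uniform(lo, hi + 1))

        # per-patient date shift: anchor admission inside the shifted window
        anchor = window_start + pd.Timedelta(
            days=int(rng.integers(0, max(window_days, 1))),
            minutes=int(rng.integers(0, 1440)))
        # admission count is independent of age band so admission-level
        # band shares match the configured patient-level weights
        n_adm = 1 + int(rng.poisson(0.268))

        first_admit = anchor
        if neonate:
            dob = first_admit - pd.Timedelta(days=float(rng.uniform(0, 3)))
        else:
            dob = first_admit - pd.Timedelta(days=age * 365.25
                                             + float(rng.uniform(0, 180)))
            # obfuscation keys on the resulting calendar age at admission
            if config.obfuscate_over_89 and \
                    first_admit.year - dob.year > 89:
                dob = first_admit - pd.DateOffset(years=300)
        dob = pd.Timestamp(_minute(_sec(dob))[()] * 10**9).normalize()
        # dates of birth are date-resolution (midnight), as in the source
        # layout, so day-floored event dates never precede them

        died_in_hosp = False
        dod = pd.NaT
        dod_hosp = pd.NaT
        current = anchor
        for a in range(n_adm):
            if died_in_hosp:
                break
            hadm_id = hadm_counter
            hadm_counter += 1
            admit = current if a == 0 else current + pd.Timedelta(
                days=float(rng.exponential(90)) + 1)
            admit = pd.Timestamp(_minute(_sec(admit))[()] * 10**9)
            los_days = float(np.clip(rng.lognormal(1.866, 0.891), 0.3, 120.0))
            disch = admit + pd.Timedelta(days=los_days)
            disch = pd.Timestamp(_minute(_sec(disch))[()] * 10**9)
            current = disch
            admit_s, disch_s = _sec(admit), _sec(disch)

            emergency = bool(rng.random() < config.emergency_fraction)
            if emergency:
                admission_type = "EMERGENCY"
            else:
                admission_type = "ELECTIVE" if rng.random() < 0.456 else "URGENT"
            edreg = edout = pd.NaT
            if emergency:
                edreg = admit - pd.Timedelta(hours=float(rng.uniform(1, 10)))
                edreg = pd.Timestamp(_minute(_sec(edreg))[()] * 10**9)
                edout = admit

            hospital_death = bool(rng.random() < 0.07)
            deathtime = pd.NaT
            if hospital_death:
                deathtime = disch
                died_in_hosp = True
                dod = deathtime
                dod_hosp = deathtime

            ethnicity = str(rng.choice(dd.ETHNICITIES))
            service = str(rng.choice(dd.SERVICES)) if not neonate else "NB"
            diagnosis_text = str(rng.choice(
                ["SEPSIS", "PNEUMONIA", "CHEST PAIN", "GI BLEED",
                 "NEWBORN", "CONGESTIVE HEART FAILURE"]))

            tables["admissions"].append(dict(
                subject_id=subject_id, hadm_id=hadm_id, admittime=admit,
                dischtime=disch, deathtime=deathtime,
                admission_type=admission_type,
                admission_location="EMERGENCY ROOM ADMIT" if emergency
                else "PHYS REFERRAL/NORMAL DELI",
                discharge_location="DEAD/EXPIRED" if hospital_death
                else "HOME",
                insurance=str(rng.choice(dd.INSURANCES)),
                language=str(rng.choice(dd.LANGUAGES)) or None,
                religion=str(rng.choice(dd.RELIGIONS)),
                marital_status=str(rng.choice(dd.MARITAL_STATUSES)),
                ethnicity=ethnicity, edregtime=edreg, edouttime=edout,
                diagnosis=diagnosis_text,
                hospital_expire_flag=int(hospital_death)))
            tables["services"].append(dict(
                subject_id=subject_id, hadm_id=hadm_id, transfertime=admit,
                prev_service=None, curr_service=service))

            # ---- transfers: ward / ICU segments -------------------------
            no_transfers = rng.random() < 0.03
            stays: list[tuple[int, int, int]] = []  # (in_s, out_s, icustay_id)
            if not no_transfers:
                n_icu = int(rng.poisson(config.mean_icu_stays_per_admission))
                segs = []  # (kind, weight)
                segs.append(("ward", float(rng.uniform(0.4, 1.0))))
                for _ in range(n_icu):
                    segs.append(("icu", float(rng.uniform(0.8, 3.0))))
                    segs.append(("ward", float(rng.uniform(0.2, 1.5))))
                total_w = sum(w for _, w in segs)
                t = admit_s
                icu_unit = dd.NICU_CAREUNIT if neonate else str(
                    rng.choice(dd.ICU_CAREUNITS))
                seg_bounds = []
                for kind, w in segs:
                    dur = max(int((disch_s - admit_s) * w / total_w), 600)
                    out = min(t + dur, disch_s)
                    seg_bounds.append((kind, t, out))
                    t = out
                # normalize: last segment ends at discharge
                if seg_bounds:
                    kind, t0, _ = seg_bounds[-1]
                    seg_bounds[-1] = (kind, t0, disch_s)
                prev_unit = None
                last_icu_out = None
                for si, (kind, t0, t1) in enumerate(seg_bounds):
                    if t1 <= t0:
                        continue
                    unit = icu_unit if kind == "icu" else None
                    icustay_id = None
                    if kind == "icu":
                        if last_icu_out is not None and \
                                t0 - last_icu_out <= 24 * 3600:
                            icustay_id = stays[-1][2]
                            stays[-1] = (stays[-1][0], t1, icustay_id)
                        else:
                            icustay_id = icustay_counter
                            icustay_counter += 1
                            stays.append((t0, t1, icustay_id))
                        last_icu_out = t1
                    tables["transfers"].append(dict(
                        subject_id=subject_id, hadm_id=hadm_id,
                        icustay_id=icustay_id, dbsource="metavision",
                        eventtype="admit" if si == 0 else "transfer",
                        prev_careunit=prev_unit, curr_careunit=unit,
                        prev_wardid=int(rng.integers(1, 60)),
                        curr_wardid=int(rng.integers(1, 60)),
                        intime=pd.Timestamp(_minute(t0)[()] * 10**9),
                        outtime=pd.Timestamp(_minute(t1)[()] * 10**9),
                        los=round((t1 - t0) / DAY, 2)))
                    prev_unit = unit
                for in_s, out_s, sid in stays:
                    tables["icustays"].append(dict(
                        subject_id=subject_id, hadm_id=hadm_id,
                        icustay_id=sid, dbsource="metavision",
                        first_careunit=icu_unit, last_careunit=icu_unit,
                        first_wardid=int(rng.integers(1, 60)),
                        last_wardid=int(rng.integers(1, 60)),
                        intime=pd.Timestamp(_minute(in_s)[()] * 10**9),
                        outtime=pd.Timestamp(_minute(out_s)[()] * 10**9),
                        los=round((out_s - in_s) / DAY, 4)))

            stay_in = np.array([s[0] for s in stays], dtype="int64")
            stay_out = np.array([s[1] for s in stays], dtype="int64")
            stay_ids = np.array([s[2] for s in stays], dtype="int64")

            def _stay_of(sec_arr):
                """icustay_id covering each time, NaN-coded as -1."""
                if len(stay_in) == 0:
                    return np.full(len(sec_arr), -1, dtype="int64")
                idx = np.searchsorted(stay_in, sec_arr, side="right") - 1
                ok = (idx >= 0) & (sec_arr < stay_out[np.clip(idx, 0, None)])
                out = np.where(ok, stay_ids[np.clip(idx, 0, None)], -1)
                return out.astype("int64")

            def _times(n):
                return _minute(admit_s + rng.random(n) * (disch_s - admit_s))

            # ---- chartevents (columnar) ---------------------------------
            n_chart = int(rng.poisson(config.mean_chart_events_per_admission))
            if n_chart:
                idx = rng.choice(len(dd.CHART_ITEMS), size=n_chart,
                                 p=_CHART_WEIGHTS)
                t = np.sort(_times(n_chart))
                vnum = np.round(chart_lo[idx] + rng.random(n_chart)
                                * (chart_hi[idx] - chart_lo[idx]), 1)
                vnum[chart_itemids[idx] == 198] = np.round(
                    vnum[chart_itemids[idx] == 198], 0)
                chart.extend(
                    subject_id=np.full(n_chart, subject_id),
                    hadm_id=np.full(n_chart, hadm_id),
                    icustay_id=_stay_of(t), itemid=chart_itemids[idx],
                    charttime=t,
                    storetime=t + rng.integers(300, 3600, n_chart),
                    cgid=rng.choice(cgids, n_chart),
                    valuenum=vnum, text_kind=chart_text[idx],
                    text_choice=rng.integers(0, 3, n_chart),
                    uom=chart_unit[idx],
                    error=np.zeros(n_chart, dtype="int64"),
                    warning=np.zeros(n_chart, dtype="int64"))

            # ---- labevents (columnar) -----------------------------------
            n_lab = int(rng.poisson(config.mean_labs_per_admission))
            if n_lab:
                idx = rng.choice(len(dd.LAB_ITEMS), size=n_lab, p=_LAB_WEIGHTS)
                t = np.sort(_times(n_lab))
                vnum = np.round(lab_lo[idx] + rng.random(n_lab)
                                * (lab_hi[idx] - lab_lo[idx]), 1)
                labs.extend(
                    subject_id=np.full(n_lab, subject_id),
                    hadm_id=np.full(n_lab, hadm_id),
                    itemid=lab_itemids[idx], charttime=t, valuenum=vnum,
                    kind=lab_kind[idx], uom=lab_unit[idx],
                    qual_choice=rng.integers(0, 3, n_lab),
                    abnormal=(rng.random(n_lab) < 0.15))

            # ---- prescriptions (columnar) -------------------------------
            n_rx = int(rng.poisson(config.mean_drugs_per_admission))
            if n_rx:
                idx = rng.integers(0, len(dd.FORMULARY), n_rx)
                start = _times(n_rx) // DAY * DAY
                dur = rng.integers(1, 8, n_rx) * DAY
                missing_end = rng.random(n_rx) < 0.10
                rx.extend(
                    subject_id=np.full(n_rx, subject_id),
                    hadm_id=np.full(n_rx, hadm_id),
                    icustay_id=_stay_of(start), drug_idx=idx,
                    startdate=start,
                    enddate=np.where(missing_end, -1, start + dur),
                    dose=np.round(rng.uniform(1, 500, n_rx), 0))

            # ---- diagnoses_icd (columnar) -------------------------------
            n_dx = max(int(rng.poisson(config.mean_diagnoses_per_admission)), 1)
            codes = rng.integers(0, len(icd9_codes), n_dx)
            if neonate:
                codes[0] = icd9_codes.index("V3000")
            dx.extend(subject_id=np.full(n_dx, subject_id),
                      hadm_id=np.full(n_dx, hadm_id),
                      seq_num=np.arange(1, n_dx + 1), code_idx=codes)

            # ---- outputevents -------------------------------------------
            for t in _times(int(rng.poisson(3.0))):
                oid = int(rng.integers(0, len(dd.OUTPUT_ITEMS)))
                tables["outputevents"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    icustay_id=int(_stay_of([t])[0]),
                    charttime=pd.Timestamp(int(t) * 10**9),
                    itemid=dd.OUTPUT_ITEMS[oid][0],
                    value=round(float(rng.uniform(30, 600)), 0),
                    valueuom="mL",
                    storetime=pd.Timestamp((int(t) + 1800) * 10**9),
                    cgid=int(rng.choice(cgids)), stopped=None,
                    newbottle=None, iserror=None))

            # ---- microbiology: one culture with susceptibility panel ----
            if rng.random() < 0.3:
                spec = dd.MICRO_SPECIMENS[int(rng.integers(0, 2))]
                org = dd.MICRO_ORGANISMS[int(rng.integers(0, 2))]
                t = pd.Timestamp(int(_times(1)[0]) * 10**9)
                base = dict(subject_id=subject_id, hadm_id=hadm_id,
                            chartdate=t.normalize(), charttime=t,
                            spec_itemid=spec[0], spec_type_desc=spec[1],
                            org_itemid=org[0], org_name=org[1], isolate_num=1)
                tables["microbiologyevents"].append(dict(
                    base, ab_itemid=None, ab_name=None, dilution_text=None,
                    dilution_comparison=None, dilution_value=None,
                    interpretation=None))
                n_ab = int(rng.integers(1, 5))
                ab_idx = rng.choice(len(dd.MICRO_ANTIBIOTICS), n_ab,
                                    replace=False)
                for ai in ab_idx:
                    ab = dd.MICRO_ANTIBIOTICS[int(ai)]
                    dil = float(rng.choice([0.25, 0.5, 1.0, 2.0, 16.0]))
                    comp = str(rng.choice(["<=", "=", ">="]))
                    tables["microbiologyevents"].append(dict(
                        base, ab_itemid=ab[0], ab_name=ab[1],
                        dilution_text=f"{comp}{dil}",
                        dilution_comparison=comp, dilution_value=dil,
                        interpretation=str(rng.choice(
                            ["S", "R", "I"], p=[0.6, 0.3, 0.1]))))

            # ---- infusions ----------------------------------------------
            for t in _times(int(rng.poisson(1.5))):
                item = dd.INPUT_ITEMS_CV[int(rng.integers(0, 3))]
                orderid_counter += 1
                tables["inputevents_cv"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    icustay_id=int(_stay_of([t])[0]),
                    charttime=pd.Timestamp(int(t) * 10**9), itemid=item[0],
                    amount=round(float(rng.uniform(10, 500)), 1),
                    amountuom="mL", rate=round(float(rng.uniform(1, 20)), 1),
                    rateuom=item[2],
                    storetime=pd.Timestamp((int(t) + 900) * 10**9),
                    cgid=int(rng.choice(cgids)), orderid=orderid_counter,
                    linkorderid=orderid_counter, stopped=None,
                    originalroute="IV"))
            for t in _times(int(rng.poisson(1.5))):
                item = dd.INPUT_ITEMS_MV[0]  # drug component
                orderid_counter += 1
                end = int(t) + int(rng.integers(1800, 6 * 3600))
                common = dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    icustay_id=int(_stay_of([t])[0]),
                    starttime=pd.Timestamp(int(t) * 10**9),
                    endtime=pd.Timestamp(end * 10**9),
                    storetime=pd.Timestamp((int(t) + 600) * 10**9),
                    cgid=int(rng.choice(cgids)), orderid=orderid_counter,
                    linkorderid=orderid_counter,
                    patientweight=round(float(rng.uniform(45, 120)), 1),
                    cancelreason=0, statusdescription="FinishedRunning")
                tables["inputevents_mv"].append(dict(
                    common, itemid=item[0],
                    amount=round(float(rng.uniform(1, 30)), 2),
                    amountuom="mg", rate=round(float(rng.uniform(0.01, 0.5)), 3),
                    rateuom=item[2], ordercategoryname="01-Drips"))
                if rng.random() < 0.5:  # solution carrying the drug
                    sol = dd.INPUT_ITEMS_MV[1 + int(rng.integers(0, 2))]
                    tables["inputevents_mv"].append(dict(
                        common, itemid=sol[0],
                        amount=round(float(rng.uniform(50, 500)), 1),
                        amountuom="mL",
                        rate=round(float(rng.uniform(10, 100)), 1),
                        rateuom=sol[2], ordercategoryname="02-Fluids"))

            # ---- procedures ---------------------------------------------
            for t in _times(int(rng.poisson(0.6))):
                item = dd.PROCEDURE_ITEMS_MV[int(rng.integers(0, 3))]
                orderid_counter += 1
                tables["procedureevents_mv"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    icustay_id=int(_stay_of([t])[0]),
                    starttime=pd.Timestamp(int(t) * 10**9),
                    endtime=pd.Timestamp((int(t) + 1800) * 10**9),
                    itemid=item[0], value=1.0, valueuom=None,
                    location=None,
                    storetime=pd.Timestamp((int(t) + 3600) * 10**9),
                    cgid=int(rng.choice(cgids)), orderid=orderid_counter,
                    linkorderid=orderid_counter, ordercategoryname=item[2],
                    cancelreason=0, statusdescription="FinishedRunning"))
            for k, t in enumerate(_times(int(rng.poisson(1.5)))):
                code = dd.ICD9_PROCEDURES[int(rng.integers(0, 3))][0]
                tables["procedures_icd"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id, seq_num=k + 1,
                    icd9_code=code))
            for k, t in enumerate(_times(int(rng.poisson(2.5)))):
                cpt = dd.CPT_CODES[int(rng.integers(0, 3))]
                tables["cptevents"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    costcenter="ICU",
                    chartdate=pd.Timestamp(int(t) * 10**9).normalize(),
                    cpt_cd=cpt[0], cpt_number=int(cpt[0]), cpt_suffix=None,
                    ticket_id_seq=k + 1, sectionheader=cpt[2],
                    subsectionheader=cpt[2], description=cpt[1]))

            # ---- notes, datetime events, drg, callout -------------------
            n_notes = max(int(rng.poisson(config.mean_notes_per_admission)), 1)
            for k, t in enumerate(_times(n_notes)):
                category = "Discharge summary" if k == 0 else str(
                    rng.choice(dd.NOTE_CATEGORIES))
                tables["noteevents"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    chartdate=pd.Timestamp(int(t) * 10**9).normalize(),
                    charttime=pd.Timestamp(int(t) * 10**9),
                    storetime=pd.Timestamp((int(t) + 7200) * 10**9),
                    category=category, description="Report",
                    cgid=int(rng.choice(cgids)), iserror=None,
                    text=_note_text(rng, category)))
            for t in _times(int(rng.poisson(1.0))):
                item = dd.DATETIME_ITEMS[int(rng.integers(0, 2))]
                tables["datetimeevents"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    icustay_id=int(_stay_of([t])[0]), itemid=item[0],
                    charttime=pd.Timestamp(int(t) * 10**9),
                    storetime=pd.Timestamp((int(t) + 600) * 10**9),
                    cgid=int(rng.choice(cgids)),
                    value=pd.Timestamp((int(t) - 3 * DAY) * 10**9),
                    valueuom="Date", warning=0, error=0,
                    resultstatus=None, stopped=None))
            drg = dd.DRG_CODES[int(rng.integers(0, 3))]
            tables["drgcodes"].append(dict(
                subject_id=subject_id, hadm_id=hadm_id, drg_type=drg[0],
                drg_code=drg[1], description=drg[2],
                drg_severity=int(rng.integers(1, 5)),
                drg_mortality=int(rng.integers(1, 5))))
            if rng.random() < 0.5:
                tables["callout"].append(dict(
                    subject_id=subject_id, hadm_id=hadm_id,
                    submit_wardid=int(rng.integers(1, 60)),
                    curr_wardid=int(rng.integers(1, 60)),
                    curr_careunit=str(rng.choice(dd.ICU_CAREUNITS)),
                    callout_wardid=int(rng.integers(1, 60)),
                    callout_service=service,
                    request_tele=int(rng.integers(0, 2)),
                    request_resp=int(rng.integers(0, 2)),
                    callout_status="Inactive",
                    callout_outcome=str(rng.choice(
                        ["Discharged", "Cancelled"])),
                    createtime=admit + pd.Timedelta(hours=12),
                    outcometime=disch))

        tables["patients"].append(dict(
            subject_id=subject_id, gender="F" if female else "M", dob=dob,
            dod=dod, dod_hosp=dod_hosp,
            expire_flag=int(not pd.isna(dod))))

    frames = {name: pd.DataFrame(rows) for name, rows in tables.items()}
    frames["chartevents"] = _finish_chartevents(chart.frame())
    frames["labevents"] = _finish_labevents(labs.frame())
    frames["prescriptions"] = _finish_prescriptions(rx.frame())
    frames["diagnoses_icd"] = _finish_diagnoses(dx.frame(), icd9_codes)
    frames["caregivers"] = pd.DataFrame(
        [dict(cgid=c, label="RN" if c % 2 else "MD",
              description="Research Nurse" if c % 2 else "Attending")
         for c in cgids])
    frames.update(_dictionary_frames())

    for name, df in frames.items():
        if len(df):
            df.insert(0, "row_id", np.arange(1, len(df) + 1))
    db = SourceDatabase(frames)
    if config.error_row_fraction > 0:
        db = inject_error_flags(db, config.error_row_fraction,
                                seed=config.seed + 777)
    return db


def _finish_chartevents(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    value = df["valuenum"].round(1).astype(str)
    texts = np.array(["Yes", "No", "Former"], dtype=object)
    is_text = df["text_kind"].astype(bool)
    value = value.where(~is_text, pd.Series(
        texts[df["text_choice"].to_numpy() % 3], index=df.index))
    out = pd.DataFrame({
        "subject_id": df["subject_id"], "hadm_id": df["hadm_id"],
        "icustay_id": df["icustay_id"].where(df["icustay_id"] >= 0),
        "itemid": df["itemid"],
        "charttime": pd.to_datetime(df["charttime"], unit="s"),
        "storetime": pd.to_datetime(_minute(df["storetime"]), unit="s"),
        "cgid": df["cgid"], "value": value,
        "valuenum": df["valuenum"].where(~is_text),
        "valueuom": df["uom"].replace("", None),
        "warning": df["warning"], "error": df["error"],
        "resultstatus": None, "stopped": None})
    return out


def _finish_labevents(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    kind = df["kind"].to_numpy()
    vnum = df["valuenum"].to_numpy(dtype=float)
    value = pd.Series(np.round(vnum, 1).astype(str), index=df.index,
                      dtype=object)
    # comparator items render as "<thr unit"; qualitative as coded text
    comp_rows = kind == 1
    if comp_rows.any():
        value.loc[comp_rows] = "<0.5 ng/mL"
    qual_choices = {51484: ("NEGATIVE", "TRACE", "SMALL"),
                    51492: ("NEG", "TR", "30")}
    qual_rows = kind == 2
    if qual_rows.any():
        items = df.loc[qual_rows, "itemid"].to_numpy()
        picks = df.loc[qual_rows, "qual_choice"].to_numpy()
        value.loc[qual_rows] = [qual_choices[i][p % 3]
                                for i, p in zip(items, picks)]
    vnum_out = np.where(kind == 0, vnum, np.nan)
    return pd.DataFrame({
        "subject_id": df["subject_id"], "hadm_id": df["hadm_id"],
        "itemid": df["itemid"],
        "charttime": pd.to_datetime(df["charttime"], unit="s"),
        "value": value, "valuenum": vnum_out,
        "valueuom": df["uom"].replace("", None),
        "flag": pd.Series(np.where(df["abnormal"], "abnormal", None),
                          index=df.index, dtype=object)})


def _finish_prescriptions(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    form = dd.FORMULARY
    idx = df["drug_idx"].to_numpy()
    return pd.DataFrame({
        "subject_id": df["subject_id"], "hadm_id": df["hadm_id"],
        "icustay_id": df["icustay_id"].where(df["icustay_id"] >= 0),
        "startdate": pd.to_datetime(df["startdate"], unit="s"),
        "enddate": pd.to_datetime(
            df["enddate"].where(df["enddate"] >= 0), unit="s"),
        "drug_type": "MAIN",
        "drug": [form[i][0] for i in idx],
        "drug_name_generic": [form[i][1] for i in idx],
        "formulary_drug_cd": None, "gsn": None,
        "ndc": [form[i][2] for i in idx],
        "prod_strength": None,
        "dose_val_rx": df["dose"].round(0).astype(int).astype(str),
        "dose_unit_rx": "mg",
        "route": [form[i][3] for i in idx]})


def _finish_diagnoses(df: pd.DataFrame, codes: list[str]) -> pd.DataFrame:
    if df.empty:
        return df
    return pd.DataFrame({
        "subject_id": df["subject_id"], "hadm_id": df["hadm_id"],
        "seq_num": df["seq_num"],
        "icd9_code": [codes[i] for i in df["code_idx"].to_numpy()]})


def _dictionary_frames() -> dict[str, pd.DataFrame]:
    d_items = []
    for itemid, label, cat, unit, kind, _ in dd.CHART_ITEMS:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="metavision", linksto="chartevents",
                            category=cat, unitname=unit,
                            param_type="Text" if kind == "text" else "Numeric"))
    for itemid, label, cat in dd.DATETIME_ITEMS:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="metavision", linksto="datetimeevents",
                            category=cat, unitname=None, param_type="Date"))
    for itemid, label, unit in dd.OUTPUT_ITEMS:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="carevue", linksto="outputevents",
                            category="Output", unitname=unit,
                            param_type="Numeric"))
    for itemid, label, unit in dd.INPUT_ITEMS_CV:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="carevue", linksto="inputevents_cv",
                            category="Input", unitname=unit,
                            param_type="Numeric"))
    for itemid, label, unit in dd.INPUT_ITEMS_MV:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="metavision", linksto="inputevents_mv",
                            category="Input", unitname=unit,
                            param_type="Numeric"))
    for itemid, label, cat in dd.PROCEDURE_ITEMS_MV:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="metavision", linksto="procedureevents_mv",
                            category=cat, unitname=None, param_type="Numeric"))
    for itemid, label in dd.MICRO_SPECIMENS + dd.MICRO_ORGANISMS \
            + dd.MICRO_ANTIBIOTICS:
        d_items.append(dict(itemid=itemid, label=label, abbreviation=label[:10],
                            dbsource="hospital", linksto="microbiologyevents",
                            category="Micro", unitname=None, param_type="Text"))
    d_labitems = [dict(itemid=i, label=lab, fluid=fluid, category=cat,
                       loinc_code=loinc)
                  for i, lab, fluid, cat, loinc, _u, _k, _p in dd.LAB_ITEMS]
    return {
        "d_items": pd.DataFrame(d_items),
        "d_labitems": pd.DataFrame(d_labitems),
        "d_icd_diagnoses": pd.DataFrame(
            [dict(icd9_code=c, short_title=t, long_title=t)
             for c, t in dd.ICD9_DIAGNOSES]),
        "d_icd_procedures": pd.DataFrame(
            [dict(icd9_code=c, short_title=t, long_title=t)
             for c, t in dd.ICD9_PROCEDURES]),
        "d_cpt": pd.DataFrame(
            [dict(category=1, sectionrange="99201-99499",
                  sectionheader="Evaluation and management",
                  subsectionrange=c, subsectionheader=t)
             for c, t, _ in dd.CPT_CODES]),
    }


def inject_error_flags(db: SourceDatabase, fraction: float,
                       seed: int) -> SourceDatabase:
    """Flag rows of the five flagged tables as erroneous/cancelled.

    Each row of INPUTEVENTS_MV, CHARTEVENTS, PROCEDUREEVENTS_MV, NOTEEVENTS
    and DATETIMEEVENTS is independently flagged with probability ``fraction``
    using the table's own convention (integer error column, ``Rewritten``
    status, or ``iserror``). Deterministic in ``seed``.
    """
    if not (0.0 <= fraction <= 1.0):
        from .config import ConfigurationError
        raise ConfigurationError(
            f"error fraction must be in [0, 1], got {fraction!r}")
    out = db.copy()
    for k, (table, (col, bad)) in enumerate(sorted(FLAG_DIALECT.items())):
        df = out.tables[table]
        if df.empty:
            continue
        rng = np.random.default_rng([seed, k])
        mask = rng.random(len(df)) < fraction
        if col == "statusdescription":
            df[col] = np.where(mask, "Rewritten", "FinishedRunning")
        else:
            df[col] = pd.array(np.where(mask, 1, 0), dtype="Int64")
        out.tables[table] = df
    return out
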
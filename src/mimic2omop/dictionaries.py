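"""Dictionary fixtures for the synthetic source database.

The item pools deliberately include the terminology corner cases the
conceptual alignment has to handle: six redundant body-temperature chart
items, laboratory items with and without LOINC codes, textual lab values,
culture organisms with antibiotic susceptibility panels, and drug codes with
and without a standard mapping.
"""

from __future__ import annotations

# itemid, label, category, unit, value kind, extra
# value kinds: "numeric" (lo, hi), "text" (choices)
CHART_ITEMS = [
    # six equivalent body-temperature items; two Celsius, four Fahrenheit
    (676, "Temperature C", "Vitals", "Deg. C", "numeric", (35.0, 40.0)),
    (677, "Temperature C (calc)", "Vitals", "Deg. C", "numeric", (35.0, 40.0)),
    (678, "Temperature F", "Vitals", "Deg. F", "numeric", (95.0, 104.0)),
    (679, "Temperature F (calc)", "Vitals", "Deg. F", "numeric", (95.0, 104.0)),
    (223761, "Temperature Fahrenheit", "Routine Vital Signs", "Deg. F", "numeric", (95.0, 104.0)),
    (223762, "Temperature Celsius", "Routine Vital Signs", "Deg. C", "numeric", (35.0, 40.0)),
    (211, "Heart Rate", "Vitals", "bpm", "numeric", (35.0, 160.0)),
    (220045, "Heart Rate", "Routine Vital Signs", "bpm", "numeric", (35.0, 160.0)),
    (51, "Arterial BP [Systolic]", "Vitals", "mmHg", "numeric", (60.0, 210.0)),
    (220179, "Non Invasive Blood Pressure systolic", "Routine Vital Signs", "mmHg", "numeric", (60.0, 210.0)),
    (618, "Respiratory Rate", "Vitals", "insp/min", "numeric", (8.0, 40.0)),
    (220210, "Respiratory Rate", "Routine Vital Signs", "insp/min", "numeric", (8.0, 40.0)),
    (646, "SpO2", "Vitals", "%", "numeric", (80.0, 100.0)),
    (220277, "O2 saturation pulseoxymetry", "Routine Vital Signs", "%", "numeric", (80.0, 100.0)),
    (198, "GCS Total", "Scores", "points", "numeric", (3.0, 15.0)),
    (226512, "Admission Weight (Kg)", "General", "kg", "numeric", (40.0, 140.0)),
    (226531, "Admission Weight (lbs.)", "General", "lbs", "numeric", (90.0, 310.0)),
    (226730, "Height (cm)", "General", "cm", "numeric", (140.0, 200.0)),
    (920, "Tobacco Use", "Social History", None, "text", ("Yes", "No", "Former")),
    # chart-side laboratory items: the second laboratory stream
    (220615, "Creatinine (serum)", "Labs", "mg/dL", "numeric", (0.4, 4.0)),
    (220645, "Sodium (serum)", "Labs", "mEq/L", "numeric", (128.0, 148.0)),
    (223830, "PH (Arterial)", "Labs", None, "numeric", (7.15, 7.60)),
]

# itemid, label, fluid, category, loinc_code (None -> no code), unit, kind
# kinds: numeric (lo, hi); comparator (threshold, unit); qualitative (choices)
LAB_ITEMS = [
    (50820, "pH", "Blood", "Blood Gas", "11558-4", "units", "numeric", (7.15, 7.60)),
    (50821, "pO2", "Blood", "Blood Gas", "11556-8", "mmHg", "numeric", (50.0, 250.0)),
    (50816, "Oxygen", "Blood", "Blood Gas", "19994-3", "%", "numeric", (21.0, 100.0)),
    (50983, "Sodium", "Blood", "Chemistry", "2951-2", "mEq/L", "numeric", (120.0, 155.0)),
    (50971, "Potassium", "Blood", "Chemistry", "2823-3", "mEq/L", "numeric", (2.4, 6.8)),
    (50912, "Creatinine", "Blood", "Chemistry", "2160-0", "mg/dL", "numeric", (0.3, 6.0)),
    (50931, "Glucose", "Blood", "Chemistry", "2345-7", "mg/dL", "numeric", (50.0, 400.0)),
    (50893, "Calcium, Total", "Blood", "Chemistry", "17861-6", "mg/dL", "numeric", (6.5, 11.5)),
    (50862, "Albumin", "Blood", "Chemistry", "1751-7", "g/dL", "numeric", (1.5, 5.0)),
    (50882, "Bicarbonate", "Blood", "Chemistry", "1963-8", "mEq/L", "numeric", (10.0, 34.0)),
    (51006, "Urea Nitrogen", "Blood", "Chemistry", "3094-0", "mg/dL", "numeric", (5.0, 90.0)),
    (51300, "WBC Count", "Blood", "Hematology", "804-5", "K/uL", "numeric", (0.5, 30.0)),
    (50885, "Bilirubin, Total", "Blood", "Chemistry", "1975-2", "mg/dL", "numeric", (0.1, 12.0)),
    (51265, "Platelet Count", "Blood", "Hematology", "777-3", "K/uL", "numeric", (30.0, 550.0)),
    (51221, "Hematocrit", "Blood", "Hematology", "4544-3", "%", "numeric", (18.0, 52.0)),
    (50974, "Prostate Specific Antigen", "Blood", "Chemistry", "2857-1", "ng/mL", "comparator", (0.5, "ng/mL")),
    (51484, "Ketone", "Urine", "Hematology", None, None, "qualitative", ("NEGATIVE", "TRACE", "SMALL")),
    (51492, "Protein", "Urine", "Chemistry", None, None, "qualitative", ("NEG", "TR", "30", "100")),
]

# itemid, label
DATETIME_ITEMS = [
    (5684, "Last dialysis", "Adm History/FHPA"),
    (225401, "Blood Cultured", "Access Lines - Invasive"),
]

OUTPUT_ITEMS = [
    (40055, "Urine Out Foley", "mL"),
    (40069, "Urine Out Void", "mL"),
]

INPUT_ITEMS_CV = [
    (30047, "Dopamine", "mcg/kg/min"),
    (30018, ".9% Normal Saline", "mL/hr"),
    (30013, "D5W", "mL/hr"),
]

# metavision infusion items; solutions participate in drug-in-solution links
INPUT_ITEMS_MV = [
    (221906, "Norepinephrine", "mcg/kg/min"),
    (225158, "NaCl 0.9%", "mL/hr"),
    (220949, "Dextrose 5%", "mL/hr"),
]
MV_SOLUTION_ITEMIDS = {225158, 220949}

PROCEDURE_ITEMS_MV = [
    (224385, "Intubation", "Intubation/Extubation"),
    (225441, "Hemodialysis", "Dialysis"),
    (225752, "Arterial Line", "Invasive Lines"),
]

# spec_itemid, description, site kind
MICRO_SPECIMENS = [
    (70012, "BLOOD CULTURE"),
    (70079, "URINE"),
]

MICRO_ORGANISMS = [
    (80002, "STAPH AUREUS COAG +"),
    (80155, "ESCHERICHIA COLI"),
]

MICRO_ANTIBIOTICS = [
    (90004, "GENTAMICIN"),
    (90008, "CEFTRIAXONE"),
    (90012, "VANCOMYCIN"),
    (90016, "OXACILLIN"),
]

# drug label, generic, ndc (None -> no code), route
FORMULARY = [
    ("Norepinephrine", "Norepinephrine Bitartrate", "00409337501", "IV"),
    ("Vancomycin", "Vancomycin HCl", "00409433301", "IV"),
    ("Heparin", "Heparin Sodium", "00641040025", "SC"),
    ("Aspirin", "Aspirin", "63739043402", "PO"),
    ("Insulin", "Insulin Regular Human", "00002821501", "SC"),
    ("Magic Mouthwash", None, None, "PO"),
]

# icd9 diagnosis code, short title; 0389 carries a one-to-two standard mapping
ICD9_DIAGNOSES = [
    ("4019", "Hypertension NOS"),
    ("25000", "DMII wo cmp nt st uncntrl"),
    ("0389", "Septicemia NOS"),
    ("41401", "Crnry athrscl natve vssl"),
    ("5849", "Acute kidney failure NOS"),
    ("51881", "Acute respiratry failure"),
    ("99591", "Sepsis"),
    ("V3000", "Single lb in-hosp"),
]

ICD9_PROCEDURES = [
    ("9604", "Insert endotracheal tube"),
    ("3995", "Hemodialysis"),
    ("9904", "Packed cell transfusion"),
]

CPT_CODES = [
    ("99291", "Critical care, first hour", "Evaluation and management"),
    ("99232", "Subsequent hospital care", "Evaluation and management"),
    ("94002", "Ventilation management, initial day", "Pulmonary"),
]

DRG_CODES = [
    ("HCFA", "470", "Major joint replacement"),
    ("HCFA", "871", "Septicemia w MV >96 hrs"),
    ("APR", "194", "Heart failure"),
]

ICU_CAREUNITS = ("MICU", "SICU", "CCU", "TSICU", "CSRU")
NICU_CAREUNIT = "NICU"

SERVICES = ("MED", "SURG", "CSURG", "NSURG", "CMED", "OMED", "NB")
SURGICAL_SERVICES = ("SURG", "CSURG", "NSURG")

ETHNICITIES = ("WHITE", "BLACK/AFRICAN AMERICAN", "HISPANIC OR LATINO",
               "ASIAN", "OTHER", "UNKNOWN/NOT SPECIFIED")
MARITAL_STATUSES = ("MARRIED", "SINGLE", "WIDOWED", "DIVORCED", "UNKNOWN")
INSURANCES = ("Medicare", "Private", "Medicaid", "Self Pay")
RELIGIONS = ("CATHOLIC", "PROTESTANT QUAKER", "JEWISH", "NOT SPECIFIED")
LANGUAGES = ("ENGL", "SPAN", "FREN", "")

NOTE_CATEGORIES = ("Discharge summary", "Nursing", "Physician", "Radiology")
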
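# mimic2omop

Transform an ICU electronic-health-record database in the 26-table
MIMIC-III v1.4 layout into the OMOP Common Data Model v5.3 — and evaluate
the result. The package is aimed at health-informatics engineers and
analysts who need a *tested, reproducible* structural + conceptual mapping
between the two models without access to the credentialed source data: a
built-in synthetic cohort generator emulates the source schema (date-shifted
timestamps, over-89 age obfuscation, error/cancel flags, neonates), so every
stage is exercised end-to-end on data the repository creates itself.

What the pipeline does:

* **Synthetic source** — cohorts with configurable marginals (gender split,
  seven age bands, emergency share, per-admission event rates), fully
  deterministic in the seed.
* **Vocabulary store** — standard concepts loaded from Athena-dialect TSV,
  implementer extension concepts in the 2.0–2.001 billion id band (e.g.
  `Labs - Culture Organisms` = 2000000007), local concepts above
  2.001 billion under vocabulary `"MIMIC code"`. Local-to-standard alignment
  resolves through four ordered cases: already standard → "Maps to"
  relationship → manual table → scored label-similarity suggestion
  (score = |T(a)∩T(b)| / √(|T(a)|·|T(b)|), standard id stays 0 until
  confirmed).
* **Structural ETL** — every clinical primary key from one global sequence
  incremented from 0; full per-row provenance; flagged-row filtering in
  exactly the five source tables that carry error/cancel flags; routing by
  the standard concept's *domain* (a chart item aligned to an
  Observation-domain concept lands in OBSERVATION); one VISIT_DETAIL row per
  transfer segment with **no** 24-hour merge of ICU re-entries; emergency
  department time as a leading segment; one SPECIMEN row per laboratory
  test; reciprocal FACT_RELATIONSHIP rows for organism↔susceptibility,
  drug↔solution and visit-detail↔care-site links.
* **Clinical derivation** — a total parser splitting textual lab values into
  operator/number/unit; temperature normalization to Celsius;
  albumin-corrected calcium `Ca + 0.8·(4 − alb)`; pH-corrected potassium
  `K + 6·(pH − 7.4)`; PaO₂/FiO₂; calculated osmolarity
  `2·Na + glu/18 + BUN/2.8`; SAPS II with mortality
  `logit⁻¹(−7.7631 + 0.0737·S + 0.9971·ln(S+1))`; denormalized tables and
  the specialized microbiology/icustays analyst tables.
* **Note NLP** — numeric-entity extraction (weight, height, BMI, LVEF) with
  0-based half-open character offsets, and section segmentation from
  templates harvested at document frequency > 1%.
* **Quality evaluation** — row/column loss accounting against a committed
  mapping specification, source-vs-CDM population characterization,
  terminology mapping coverage, and a fixed list of plausibility checks
  with error/warning/notification severities.

## Worked example

```bash
python examples/03_concept_alignment.py
```

prints the four alignment cases:

```
          Sodium -> case=already_standard standard=3019550    route=MEASUREMENT  local code is standard LOINC 2951-2
  Septicemia NOS -> case=via_relationship standard=132797     route=CONDITION_OCCURRENCE  via Maps to (2 targets, lowest id chosen by convention)
   Temperature F -> case=manual           standard=3020891    route=MEASUREMENT  temperature Fahrenheit variant; values normalized to Celsius
   PH (Arterial) -> case=suggested        standard=0          route=MEASUREMENT  suggest 3014605 (pH of Blood)
```

A LOINC-coded lab is its own standard concept; the ICD-9 code 0389 follows
its "Maps to" relationships (two targets — one CDM row is emitted per
target, the decision records both); the Fahrenheit temperature variant is
mapped manually onto the single standard body-temperature concept with value
normalization; and an unresolved item only gets a scored suggestion while
its standard id remains 0. The full pipeline is one command:

```bash
mimic2omop all --seed 7 --n-patients 100 --out out/
```

which writes the source bundle, the OMOP CSV bundle, the transform report
with provenance, derived/NLP tables and the quality report. On that run the
quality summary ends with `0 errors, 0 warnings, 2 notifications` — the
notifications count the deliberately obfuscated ages and the
observation-table rows kept under local codes. Other examples
(`examples/*.py`) cover cohort generation, the ETL loss table, SAPS II
scoring (a ventilated septic patient scores 65 points, predicted mortality
76.9%), antibiogram query equivalence, and note extraction (`Wt: 176 lb`
becomes 79.83 kg at exact character offsets).

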
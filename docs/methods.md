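# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic data does and does not emulate, and the
known limitations.

## The transformation model

The pipeline maps a 26-table ICU source layout (MIMIC-III v1.4 schema) onto
the OMOP CDM v5.3 clinical tables. Two principles organize the design:

1. **Conceptual before structural.** Every local item (chart item, lab
   item, ICD-9/CPT/NDC code) is first registered as a *local concept* and
   aligned to the standard vocabularies; the standard concept's domain then
   decides the target table. This is why a chart item aligned to an
   Observation-domain concept (tobacco use) is stored in OBSERVATION even
   though chart events default to MEASUREMENT.
2. **Nothing is lost silently.** One global integer sequence (starting at
   0) keys every emitted clinical row; each row carries a provenance link
   to its source row; rows removed by the error/cancel filters are counted
   with a reason. The invariant `input = linked + dropped` holds per source
   table and is enforced by tests and by the quality report.

### Concept id bands

| band | range | meaning |
|---|---|---|
| standard | < 2,000,000,000 | Athena-loaded vocabulary concepts |
| extension | [2,000,000,000, 2,001,000,000) | implementer-added concepts from a fixed registry (`data/extension_registry.csv`); ids are stable across runs |
| local | ≥ 2,001,000,001 | source-specific concepts, vocabulary `"MIMIC code"`, allocated sequentially |

The local band starts just above the extension band so the two can never
collide; the registry pins the culture-organism and culture-sensitivity
measurement types at 2000000007 and 2000000008, which the microbiology
model and its queries rely on.

### Alignment

Case order: (1) the local code is itself a standard concept (LOINC labs);
(2) a "Maps to" relationship exists (ICD9→SNOMED, NDC→RxNorm,
CPT4→SNOMED) — with several targets, one CDM row is emitted per target and
the decision records the full set, the lowest id being the nominal target
(a convention; the ordering of multi-target maps is not otherwise
determined); (3) a versioned manual mapping table
(`data/manual_concept_map.csv`); (4) a scored label-similarity suggestion.
The similarity is deliberately engine-independent: lower-case, strip
punctuation, token sets, `|A∩B| / sqrt(|A||B|)`, plus 0.05 (capped at 1)
for exact normalized-string equality. Suggested and unmapped decisions
both carry standard id 0; the sub-case (no equivalent / not yet mapped /
value missing) lives in the decision comment.

### Visits

One VISIT_OCCURRENCE per admission. VISIT_DETAIL holds one row per
transfer segment, chained by `preceding_visit_detail_id`; ICU segments
carry the intensive-care visit concept and are **never merged**, even when
the patient returns to the ICU within 24 hours — the source's derived stay
table (which does merge) is deliberately not transformed, so the segment
count is always ≥ the merged count. Emergency-department time becomes a
leading segment (an extension concept), and the visit interval starts at
ED registration so details are always contained in their visit. An
admission with no transfer rows receives one synthetic segment covering
the admission, keeping the chain total. Care sites are created on demand
from ICU units, wards and services.

### Measurements, specimens, microbiology

MEASUREMENT unions four sources (chart, lab, output, microbiology events).
Textual lab values go through a total parser (comparator, decimal, unit,
residual); the six redundant body-temperature items all map to the single
standard concept with Fahrenheit values converted to Celsius (rounded to
0.1); pound-denominated weights convert to kg. Because the source has no
sample identity, one SPECIMEN row is fabricated per laboratory or
microbiology measurement. A culture is modeled as an organism measurement
(concept = the culture test, value = the organism) linked by reciprocal
FACT_RELATIONSHIP rows to its susceptibility measurements (concept = the
antibiotic test, value = the S/I/R interpretation, dilution split into
operator and number). The flattened `microbiology` analyst table answers
the same panel queries without the joins, and a property test holds the
two routes equal.

### Derived values and SAPS II

Formulas not fixed by the transformation itself use the standard clinical
definitions, stated here so they can be swapped: Payne albumin correction
for calcium (`+0.8 mg/dL per g/dL below 4`); potassium corrected 0.6 mEq/L
per 0.1 pH unit from 7.4 (valid pH 6.5–8.0); calculated osmolarity
`2·Na + glucose/18 + BUN/2.8`; FiO₂ values above 1 are treated as percent.
Derived rows are appended to MEASUREMENT under extension concepts with a
derived-value type and provenance to their primary input's source row.

SAPS II uses the published point bands, committed as data
(`data/saps2_points.csv`, half-open intervals `[lo, hi)`), the serum-urea
component expressed in BUN mg/dL, and the mortality logit
`−7.7631 + 0.0737·S + 0.9971·ln(S+1)`. The per-stay calculator takes the
*worst* value per component (the value maximizing points) over the first
24 ICU hours, sums urine output, scores the P/F ratio only for ventilated
stays (ventilation inferred from intubation/ventilation-management
procedures in the same visit), and classifies admission type from the
visit's admission-type/service source value (elective + surgical service →
scheduled surgical). Missing components score 0 and are counted. Scores
land in COHORT_ATTRIBUTE under the severity-score extension concept.

### Note pipelines

Offsets are 0-based, half-open, *character* offsets — unambiguous for
multi-byte text — and `note[begin:end] == snippet` is a tested invariant.
The section harvester is a pure regex + frequency implementation:
candidates are line-initial phrases of ≤ 5 words (letters/spaces) ending in
a colon, case-normalized, kept at document frequency > 1%, minus a
committed stop-list of known false positives (measurement labels, dates).
Sections partition each note (preamble + one span per matched header) and
are not mapped to any document ontology.

## The synthetic generator

The generator's defaults are the study conditions of the source ICU
population: female share 43.85%, age-band weights
(13.75, 0.01, 2.43, 10.11, 29.45, 26.78, 17.47)%, emergency share 71.33%,
1.21 ICU stays, 478 laboratory events, 82.8 drug exposures and 11
discharge diagnoses per admission; hospital length of stay is log-normal
with median ≈ 6.5 days and quartiles ≈ 3.7/11.8 days, hospital mortality
≈ 7%. Chart density (30 events/admission) and note volume (1.5/admission)
are package choices for a light but fully exercised chart/note stream.
De-identification artifacts are emulated: all timestamps shifted into a
per-patient window (default calendar years 2100–2200), date-resolution
births, ages over 89 moved to ≈ 300 years, and a neonatal subpopulation
(NICU stays, newborn service) filling the 0–5 band. Error/cancel flags use
each table's own dialect: integer `error` (chart/datetime events),
`statusdescription = "Rewritten"` (metavision input/procedure events),
`iserror` (notes).

What the generator does **not** emulate — and hence what green tests do
not show about real data: longitudinal physiology (values are i.i.d.
within reference-spanning ranges), realistic chart density, dual
CareVue/MetaVision semantics beyond the presence of both tables, free-text
variability of real notes, and the selection process of any
"representative" development subset. Statistical claims are limited to the
configured marginals, which are tested with exact binomial/multinomial
oracles at α = 0.001 (99%/99.9% intervals).

## Numerical conventions

* Quantiles (LOS medians/IQRs): linear interpolation between closest
  ranks.
* Percentages printed at integer precision use round-half-up; row-loss
  percentages keep 4 decimals so small injected fractions survive.
* Mean age excludes obfuscated (> 150-year) ages but counts those
  admissions in the > 80 band.
* Derived values are stored at 2 decimals, temperatures at 1.
* Timestamps are minute-resolution, carried verbatim (no timezone math);
  intervals are closed at the start, open at the end.
* Ages are computed from calendar components (year + day-of-year) because
  a 300-year obfuscated interval overflows nanosecond timedeltas.
* CSV dialect: comma, double-quote quoting, empty string = null, datetimes
  `YYYY-MM-DD HH:MM:SS`; vocabulary input is tab-separated with `YYYYMMDD`
  dates.

## Quality evaluation

Row loss comes from the transform report; column loss from the committed
mapping specification (`data/mapping_spec.csv`), in which every source
column is `mapped`, `consumed` (steers the ETL — filter flags, routing
columns — without landing in a target) or `dropped` with a reason. The
derived stay table is reported as not transformed rather than lost, since
its content is reconstructed from transfers. The source-vs-CDM
characterization comparator demands exact equality on invariant items
(persons, admissions, gender, age bands, admission types) and declares a
rationale for every tolerance item (e.g. CDM laboratory rows ≥ source
because the chart-side laboratory stream joins in; CDM ICU stays ≥ source
because re-entries are not merged). Plausibility checks use the
error/warning/notification trichotomy; a clean synthetic run yields zero
errors, with notifications for obfuscated ages and local-coded tables.

## Problem sizes

The test suite and the acceptance script run on cohorts the repository
generates: 500 patients at the default study conditions for the
conservation/integrity/visit checks (~390k source rows), 2000 patients
with a lighter event stream for marginal recovery, 20 independent
12-patient cohorts for the antibiogram equivalence property, and 40-patient
runs for byte-level determinism. These sizes were chosen as the smallest
that keep every statistical oracle well-powered.

## Known limitations

* The callout workflow is reduced to a minimal COHORT_ATTRIBUTE
  projection (person, interval, telemetry request); its full semantics are
  not modeled.
* Chronic-disease points in SAPS II are wired but score 0 on the shipped
  fixture vocabulary, which contains no cancer/AIDS concepts.
* The fixture vocabulary is a small synthetic stand-in for a full Athena
  export: coverage percentages computed on it characterize the pipeline,
  not any real terminology.
* Infusion rates, provider links on events, and payer/cost information are
  declared dropped in the mapping specification rather than modeled.
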
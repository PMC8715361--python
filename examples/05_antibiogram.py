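"""Query an antibiogram two ways and confirm they agree.

A cultured organism is linked to its susceptibility tests through
reciprocal FACT_RELATIONSHIP rows; the flattened microbiology table
answers the same question without the joins.  Both routes must return the
same antibiotic panel.
"""

from mimic2omop import (GeneratorConfig, antibiogram_by_denormalized,
                        antibiogram_by_fact_relationship,
                        build_microbiology_table, generate_source, run_etl)

db = generate_source(GeneratorConfig(n_patients=60, seed=11,
                                     mean_labs_per_admission=5.0,
                                     mean_drugs_per_admission=2.0))
result = run_etl(db)
micro = build_microbiology_table(result.cdm)

STAPH = 4149419            # Staph aureus coag +
BLOOD_CULTURE = 46235217   # bacteria identified in blood by culture

via_facts = antibiogram_by_fact_relationship(result.cdm, STAPH,
                                             BLOOD_CULTURE)
via_table = antibiogram_by_denormalized(micro, STAPH, BLOOD_CULTURE)
print("antibiotics tested against Staph aureus in blood cultures:")
print("  fact-relationship route:", sorted(via_facts))
print("  denormalized route:     ", sorted(via_table))
print("routes agree:", via_facts == via_table)
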
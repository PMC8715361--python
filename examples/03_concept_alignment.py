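"""Align local source concepts to standard vocabulary concepts.

Shows the four alignment cases: a LOINC-coded lab that is already
standard, an ICD-9 code resolved through a "Maps to" relationship, a chart
item from the manual mapping table, and an item that only gets a scored
suggestion (standard id stays 0 until confirmed).
"""

from mimic2omop import VocabularyStore

store = VocabularyStore.fixture()

cases = [
    ("Sodium", "Measurement", "d_labitems", "2951-2", "LOINC"),
    ("Septicemia NOS", "Condition", "d_icd_diagnoses", "0389", "ICD9CM"),
    ("Temperature F", "Measurement", "d_items", "678", None),
    ("PH (Arterial)", "Measurement", "d_items", "223830", None),
]
for name, domain, table, code, vocab in cases:
    local = store.register_local_concept(name, domain, table, code=code,
                                         code_vocabulary=vocab)
    d = store.align_concept(local)
    route = store.domain_route(d, "MEASUREMENT")
    print(f"{name:>16} -> case={d.case_tag:<16} standard="
          f"{d.standard_concept_id:<10} route={route}  {d.comment}")
# The one-to-many ICD-9 case ("0389") resolves to the lowest target id by
# convention; its decision records both targets.
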
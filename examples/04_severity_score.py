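"""Score one ICU stay with SAPS II and read off predicted mortality.

The score sums fixed point bands over the worst values of the first 24
ICU hours plus chronic-disease and admission-type points; mortality comes
from the published logistic equation.
"""

from mimic2omop import Saps2Input, saps2

stay = Saps2Input(
    age=67, heart_rate=122, systolic_bp=88, temperature=39.2,
    ventilated=True, pf_ratio=185, urine_output=0.6, bun=42, wbc=21.5,
    potassium=5.3, sodium=129, bicarbonate=17, bilirubin=2.1, gcs=10,
    chronic="none", admission="medical")

result = saps2(stay)
print(f"SAPS II score: {result.score}")
print(f"predicted in-hospital mortality: {result.mortality:.1%}")
for component, points in sorted(result.components.items()):
    if points:
        print(f"  {component}: {points}")
# Each listed component contributes its band's points; missing components
# would score 0 and be reported in result.missing.
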
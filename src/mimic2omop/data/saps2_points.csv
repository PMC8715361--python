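component,lower,upper,points
age,0,40,0
age,40,60,7
age,60,70,12
age,70,75,15
age,75,80,16
age,80,,18
heart_rate,0,40,11
heart_rate,40,70,2
heart_rate,70,120,0
heart_rate,120,160,4
heart_rate,160,,7
systolic_bp,0,70,13
systolic_bp,70,100,5
systolic_bp,100,200,0
systolic_bp,200,,2
temperature,0,39,0
temperature,39,,3
pf_ratio,0,100,11
pf_ratio,100,200,9
pf_ratio,200,,6
urine_output,0,0.5,11
urine_output,0.5,1.0,4
urine_output,1.0,,0
bun,0,28,0
bun,28,84,6
bun,84,,10
wbc,0,1,12
wbc,1,20,0
wbc,20,,3
potassium,0,3,3
potassium,3,5,0
potassium,5,,3
sodium,0,125,5
sodium,125,145,0
sodium,145,,1
bicarbonate,0,15,6
bicarbonate,15,20,3
bicarbonate,20,,0
bilirubin,0,4,0
bilirubin,4,6,4
bilirubin,6,,9
gcs,3,6,26
gcs,6,9,13
gcs,9,11,7
gcs,11,14,5
gcs,14,16,0
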
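header
wt
ht
weight
height
bmi
ef
lvef
date
time
name
dr
tel
phone
admission date
discharge date
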
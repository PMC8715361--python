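quantity,input_1,input_2,input_3,expected
corrected_calcium,9.0,4.0,,9.0
corrected_calcium,8.0,2.0,,9.6
corrected_calcium,10.0,5.0,,9.2
corrected_calcium,7.5,3.1,,8.22
corrected_potassium,4.0,7.4,,4.0
corrected_potassium,4.0,7.5,,4.6
corrected_potassium,5.0,7.2,,3.8
corrected_potassium,3.2,7.35,,2.9
pf_ratio,100,1.0,,100
pf_ratio,80,0.4,,200
pf_ratio,80,40,,200
pf_ratio,95,0.5,,190
calculated_osmolarity,140,90,14,290
calculated_osmolarity,0,0,0,0
calculated_osmolarity,140,0,0,280
calculated_osmolarity,130,180,28,280
normalize_temperature,98.6,F,,37.0
normalize_temperature,212,F,,100.0
normalize_temperature,37.0,C,,37.0
normalize_temperature,100.4,F,,38.0
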
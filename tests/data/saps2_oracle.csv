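patient,age,heart_rate,systolic_bp,temperature,ventilated,pf_ratio,urine_output,bun,wbc,potassium,sodium,bicarbonate,bilirubin,gcs,chronic,admission,expected_score
1,35,80,120,37,0,,1.5,20,8,4,138,24,0.8,15,none,scheduled_surgical,0
2,45,125,95,39.5,1,150,0.7,30,25,5.5,120,18,5,12,none,medical,67
3,82,30,60,36,1,80,0.3,90,0.5,2.5,150,12,7,3,metastatic_cancer,unscheduled_surgical,148
4,65,65,210,38,0,,1.0,25,15,3.5,132,21,2,14,hematologic_malignancy,medical,32
5,72,170,100,39,1,250,2,84,20,3,125,15,4,9,aids,medical,81
6,40,40,70,38.9,0,,0.5,27.9,1,4.9,144,20,3.9,11,none,unscheduled_surgical,31
7,59.9,119,199,37,1,199,0.999,83,19.9,5,145,19,5.9,13,none,medical,48
8,60,70,69,40,1,100,0.49,28,21,2.9,124,14.9,6,6,metastatic_cancer,medical,108
9,16,159,199,38.9,0,,,,12,4.2,139,26,1,15,none,scheduled_surgical,4
10,75,110,85,38.5,1,,1.2,40,11,5.1,146,22,0.5,10,none,unscheduled_surgical,46
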
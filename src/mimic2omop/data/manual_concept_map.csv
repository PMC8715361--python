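source_table,local_code,standard_concept_id,score,comment
d_items,676,3020891,1.0,temperature Celsius variant
d_items,677,3020891,1.0,temperature Celsius calculated variant
d_items,678,3020891,1.0,temperature Fahrenheit variant; values normalized to Celsius
d_items,679,3020891,1.0,temperature Fahrenheit calculated variant; values normalized
d_items,223761,3020891,1.0,temperature Fahrenheit variant; values normalized
d_items,223762,3020891,1.0,temperature Celsius variant
d_items,211,3027018,1.0,heart rate
d_items,220045,3027018,1.0,heart rate metavision
d_items,51,3004249,1.0,arterial systolic blood pressure
d_items,220179,3004249,0.9,non-invasive systolic blood pressure
d_items,618,3024171,1.0,respiratory rate
d_items,220210,3024171,1.0,respiratory rate metavision
d_items,646,3016502,1.0,pulse oximetry oxygen saturation
d_items,220277,3016502,1.0,pulse oximetry oxygen saturation metavision
d_items,198,3032652,1.0,Glasgow coma score total
d_items,226512,3025315,1.0,admission weight in kg
d_items,226531,3025315,0.9,admission weight in pounds; values normalized to kg
d_items,226730,3036277,1.0,height in cm
d_items,920,4041306,0.8,tobacco use; observation domain
d_items,220615,3016723,1.0,serum creatinine charted in ICU
d_items,220645,3019550,1.0,serum sodium charted in ICU
d_items,40055,3014315,1.0,urine output via foley
d_items,40069,3014315,1.0,urine output voided
d_items,30047,1343916,0.9,dopamine mapped to closest vasopressor record kept local
d_items,30018,967823,1.0,normal saline 0.9%
d_items,30013,1560524,0.9,dextrose 5% in water
d_items,221906,1343916,1.0,norepinephrine infusion
d_items,225158,967823,1.0,sodium chloride 0.9% infusion
d_items,220949,1560524,1.0,dextrose 5% infusion
d_items,224385,4202832,1.0,intubation procedure
d_items,225441,4032243,1.0,hemodialysis procedure
d_items,225752,4046735,1.0,arterial line insertion
d_items,70012,46235217,1.0,blood culture specimen test
d_items,70079,3018190,1.0,urine culture specimen test
d_items,80002,4149419,1.0,staphylococcus aureus coagulase positive
d_items,80155,4011683,1.0,escherichia coli
d_items,90004,3011526,1.0,gentamicin susceptibility
d_items,90008,3013955,1.0,ceftriaxone susceptibility
d_items,90012,3000684,1.0,vancomycin susceptibility
d_items,90016,3009532,1.0,oxacillin susceptibility
micro_interpretation,S,45877985,1.0,susceptible
micro_interpretation,R,45878584,1.0,resistant
micro_interpretation,I,45881802,1.0,intermediate
lab_fluid,Blood,4048506,1.0,blood specimen
lab_fluid,Urine,4046227,1.0,urine specimen
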
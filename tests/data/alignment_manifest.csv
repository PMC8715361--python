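source_table,local_code,expected_case,expected_standard_id
d_items,676,manual,3020891
d_items,677,manual,3020891
d_items,678,manual,3020891
d_items,679,manual,3020891
d_items,223761,manual,3020891
d_items,223762,manual,3020891
d_items,211,manual,3027018
d_items,51,manual,3004249
d_items,618,manual,3024171
d_items,646,manual,3016502
d_items,198,manual,3032652
d_items,226512,manual,3025315
d_items,226531,manual,3025315
d_items,226730,manual,3036277
d_items,920,manual,4041306
d_items,220615,manual,3016723
d_items,223830,suggested,0
d_labitems,50820,already_standard,3014605
d_labitems,50821,already_standard,3013290
d_labitems,50816,already_standard,3020716
d_labitems,50983,already_standard,3019550
d_labitems,50971,already_standard,3023103
d_labitems,50931,already_standard,3004501
d_labitems,50893,already_standard,3006906
d_labitems,50862,already_standard,3024561
d_labitems,50882,already_standard,3016293
d_labitems,51006,already_standard,3013682
d_labitems,51300,already_standard,3010813
d_labitems,50885,already_standard,3024128
d_labitems,51484,suggested,0
d_labitems,51492,suggested,0
d_icd_diagnoses,4019,via_relationship,320128
d_icd_diagnoses,25000,via_relationship,201826
d_icd_diagnoses,0389,via_relationship,132797
d_icd_diagnoses,41401,via_relationship,317576
d_icd_diagnoses,5849,via_relationship,197320
d_icd_diagnoses,51881,via_relationship,319049
d_icd_diagnoses,99591,via_relationship,132797
d_icd_diagnoses,V3000,unmapped,0
d_icd_procedures,9604,via_relationship,4202832
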
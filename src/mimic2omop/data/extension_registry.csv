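concept_id,concept_name,domain_id
2000000001,Bed Transfer,Visit
2000000002,Room Transfer,Visit
2000000003,Emergency Department Stay,Visit
2000000004,Ward Stay,Visit
2000000005,Intensive Care Unit Stay,Visit
2000000006,Labs - Chemistry,Type Concept
2000000007,Labs - Culture Organisms,Type Concept
2000000008,Labs - Culture Sensitivity,Type Concept
2000000009,Chart - Vital Signs,Type Concept
2000000010,Chart - Laboratory,Type Concept
2000000011,Note-derived Value,Type Concept
2000000012,Derived Value,Type Concept
2000000013,Severity Score,Type Concept
2000000014,Output Events,Type Concept
2000000015,Callout Request,Observation
2000000016,Has susceptibility test,Metadata
2000000017,Susceptibility test of,Metadata
2000000018,Drug in solution,Metadata
2000000019,Solution contains drug,Metadata
2000000020,Located at care site,Metadata
2000000021,Care site of visit detail,Metadata
2000000022,Datetime Events,Type Concept
2000000023,Drg Code,Observation
2000000024,Corrected Serum Calcium,Measurement
2000000025,Corrected Serum Potassium,Measurement
2000000026,Calculated Osmolarity,Measurement
2000000027,PaO2 FiO2 Ratio,Measurement
2000000028,SAPS II Score,Measurement
2000000029,SAPS II Predicted Mortality,Measurement
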
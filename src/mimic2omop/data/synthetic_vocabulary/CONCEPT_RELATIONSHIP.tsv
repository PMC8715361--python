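concept_id_1	concept_id_2	relationship_id	valid_start_date	valid_end_date	invalid_reason
44820001	320128	Maps to	19700101	20991231	
44820002	201826	Maps to	19700101	20991231	
44820003	132797	Maps to	19700101	20991231	
44820003	434821	Maps to	19700101	20991231	
44820004	317576	Maps to	19700101	20991231	
44820005	197320	Maps to	19700101	20991231	
44820006	319049	Maps to	19700101	20991231	
44820007	132797	Maps to	19700101	20991231	
44830001	4202832	Maps to	19700101	20991231	
44830002	4032243	Maps to	19700101	20991231	
44830003	4163216	Maps to	19700101	20991231	
2514435	4148805	Maps to	19700101	20991231	
2514436	4036217	Maps to	19700101	20991231	
2514437	4230167	Maps to	19700101	20991231	
44920001	1343916	Maps to	19700101	20991231	
44920002	1838573	Maps to	19700101	20991231	
44920003	1367571	Maps to	19700101	20991231	
44920004	1112807	Maps to	19700101	20991231	
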
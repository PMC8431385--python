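id	type	label	go_terms
G00002	gene	G00002	
G00004	gene	G00004	
G00015	gene	G00015	
G00017	gene	G00017	
G00020	gene	G00020	
G00022	gene	G00022	
G00028	gene	G00028	
G00032	gene	G00032	
G00039	gene	G00039	
G00040	gene	G00040	
G00045	gene	G00045	
G00049	gene	G00049	
G00052	gene	G00052	
G00057	gene	G00057	
G00060	gene	G00060	
G00063	gene	G00063	
G00066	gene	G00066	
G00070	gene	G00070	
G00073	gene	G00073	
G00074	gene	G00074	
G00096	gene	G00096	
G00098	gene	G00098	
G00107	gene	G00107	
G00109	gene	G00109	
G00111	gene	G00111	
G00112	gene	G00112	
G00114	gene	G00114	
G00117	gene	G00117	
G00118	gene	G00118	
G00122	gene	G00122	
G00126	gene	G00126	
G00127	gene	G00127	
G00129	gene	G00129	
G00130	gene	G00130	
G00136	gene	G00136	
G00139	gene	G00139	
G00154	gene	G00154	
G00157	gene	G00157	
G00163	gene	G00163	
G00169	gene	G00169	
G00172	gene	G00172	
G00176	gene	G00176	
G00190	gene	G00190	
G00193	gene	G00193	
G00196	gene	G00196	
G00211	gene	G00211	
G00260	gene	G00260	
G00273	gene	G00273	
G00274	gene	G00274	
G00275	gene	G00275	
G00311	gene	G00311	
G00312	gene	G00312	
G00319	gene	G00319	
G00326	gene	G00326	
G00333	gene	G00333	
G00338	gene	G00338	
G00368	gene	G00368	
G00379	gene	G00379	
G00391	gene	G00391	
G00398	gene	G00398	
G00402	gene	G00402	
G00436	gene	G00436	
G00438	gene	G00438	
G00446	gene	G00446	
G00475	gene	G00475	
G00494	gene	G00494	
G00500	gene	G00500	
G00515	gene	G00515	
G00578	gene	G00578	
G00584	gene	G00584	
G00849	gene	G00849	
G00871	gene	G00871	
G00895	gene	G00895	
G00916	gene	G00916	
G00968	gene	G00968	
G00990	gene	G00990	
G01034	gene	G01034	
G01062	gene	G01062	
G01076	gene	G01076	
G01103	gene	G01103	
G01104	gene	G01104	
G01139	gene	G01139	
G01151	gene	G01151	
G01155	gene	G01155	
G01175	gene	G01175	
G01180	gene	G01180	
G01200	gene	G01200	
G01252	gene	G01252	
G01274	gene	G01274	
G01284	gene	G01284	
G01285	gene	G01285	
G01409	gene	G01409	
G01543	gene	G01543	
G01602	gene	G01602	
G01607	gene	G01607	
G01625	gene	G01625	
G01630	gene	G01630	
G01657	gene	G01657	
G01659	gene	G01659	
G01667	gene	G01667	
G01710	gene	G01710	
G01758	gene	G01758	
G01787	gene	G01787	
G01803	gene	G01803	
G01821	gene	G01821	
G01918	gene	G01918	
G01968	gene	G01968	
P000	pathway	synthetic pathway 0	GO:0006915
P001	pathway	synthetic pathway 1	GO:0006915
P006	pathway	synthetic pathway 6	GO:0006974
P009	pathway	synthetic pathway 9	GO:0006915,GO:0006954
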
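source	target
P000	G00002
P000	G00004
P000	G00020
P000	G00022
P000	G00028
P000	G00032
P000	G00049
P000	G00066
P000	G00070
P000	G00107
P000	G00139
P000	G00176
P000	G00196
P000	G00871
P000	G00990
P000	G01034
P000	G01139
P000	G01155
P000	G01175
P000	G01200
P000	G01252
P000	G01625
P000	G01659
P000	G01710
P000	G01758
P000	G01968
P001	G00017
P001	G00039
P001	G00040
P001	G00052
P001	G00057
P001	G00060
P001	G00063
P001	G00073
P001	G00074
P001	G00098
P001	G00111
P001	G00112
P001	G00117
P001	G00118
P001	G00126
P001	G00127
P001	G00129
P001	G00130
P001	G00154
P001	G00163
P001	G00169
P001	G00895
P001	G00916
P001	G01062
P001	G01076
P001	G01103
P001	G01104
P001	G01180
P001	G01274
P001	G01284
P001	G01285
P001	G01409
P001	G01543
P001	G01787
P001	G01821
P006	G00402
P006	G00436
P006	G00438
P006	G00446
P006	G00475
P006	G00494
P006	G00500
P006	G00515
P006	G00578
P006	G00584
P006	G00849
P006	G00968
P006	G01151
P006	G01602
P006	G01607
P006	G01630
P006	G01657
P006	G01667
P006	G01803
P006	G01918
P009	G00015
P009	G00020
P009	G00045
P009	G00052
P009	G00096
P009	G00107
P009	G00109
P009	G00114
P009	G00122
P009	G00136
P009	G00157
P009	G00169
P009	G00172
P009	G00190
P009	G00193
P009	G00211
P009	G00260
P009	G00273
P009	G00274
P009	G00275
P009	G00311
P009	G00312
P009	G00319
P009	G00326
P009	G00333
P009	G00338
P009	G00368
P009	G00379
P009	G00391
P009	G00398
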
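P000	contains	G00002
P000	contains	G00004
P000	contains	G00020
P000	contains	G00022
P000	contains	G00028
P000	contains	G00032
P000	contains	G00049
P000	contains	G00066
P000	contains	G00070
P000	contains	G00107
P000	contains	G00139
P000	contains	G00176
P000	contains	G00196
P000	contains	G00871
P000	contains	G00990
P000	contains	G01034
P000	contains	G01139
P000	contains	G01155
P000	contains	G01175
P000	contains	G01200
P000	contains	G01252
P000	contains	G01625
P000	contains	G01659
P000	contains	G01710
P000	contains	G01758
P000	contains	G01968
P001	contains	G00017
P001	contains	G00039
P001	contains	G00040
P001	contains	G00052
P001	contains	G00057
P001	contains	G00060
P001	contains	G00063
P001	contains	G00073
P001	contains	G00074
P001	contains	G00098
P001	contains	G00111
P001	contains	G00112
P001	contains	G00117
P001	contains	G00118
P001	contains	G00126
P001	contains	G00127
P001	contains	G00129
P001	contains	G00130
P001	contains	G00154
P001	contains	G00163
P001	contains	G00169
P001	contains	G00895
P001	contains	G00916
P001	contains	G01062
P001	contains	G01076
P001	contains	G01103
P001	contains	G01104
P001	contains	G01180
P001	contains	G01274
P001	contains	G01284
P001	contains	G01285
P001	contains	G01409
P001	contains	G01543
P001	contains	G01787
P001	contains	G01821
P006	contains	G00402
P006	contains	G00436
P006	contains	G00438
P006	contains	G00446
P006	contains	G00475
P006	contains	G00494
P006	contains	G00500
P006	contains	G00515
P006	contains	G00578
P006	contains	G00584
P006	contains	G00849
P006	contains	G00968
P006	contains	G01151
P006	contains	G01602
P006	contains	G01607
P006	contains	G01630
P006	contains	G01657
P006	contains	G01667
P006	contains	G01803
P006	contains	G01918
P009	contains	G00015
P009	contains	G00020
P009	contains	G00045
P009	contains	G00052
P009	contains	G00096
P009	contains	G00107
P009	contains	G00109
P009	contains	G00114
P009	contains	G00122
P009	contains	G00136
P009	contains	G00157
P009	contains	G00169
P009	contains	G00172
P009	contains	G00190
P009	contains	G00193
P009	contains	G00211
P009	contains	G00260
P009	contains	G00273
P009	contains	G00274
P009	contains	G00275
P009	contains	G00311
P009	contains	G00312
P009	contains	G00319
P009	contains	G00326
P009	contains	G00333
P009	contains	G00338
P009	contains	G00368
P009	contains	G00379
P009	contains	G00391
P009	contains	G00398
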
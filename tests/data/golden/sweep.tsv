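term_id	1/2	3/5	7/10	4/5	ora
GO:0006915	5	3	2	1	6
GO:0006954	2	0	0	0	3
GO:0006974	2	1	1	1	2
GO:0006979	2	1	0	0	2
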
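Condition	Significant	Toxicity	apoptotic process	inflammatory response	cellular response to DNA damage stimulus	response to oxidative stress
Pathways	60	10	5	2	2	2
THP1_low	2	2	2	0	0	0
THP1_high	4	4	3	1	1	0
SAE_low	1	1	0	1	0	0
SAE_high	3	3	0	1	1	1
Caco2_low	2	2	2	1	0	0
Caco2_high	3	3	2	0	0	1
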
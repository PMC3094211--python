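node_id	START	G1	S	G2	M	stationary_G1
CLN3	0.9	0.1	0.1	0.1	0.1	0.1
CLN1	0.1	0.3666666666666667	0.9	0.9	0.30000000000000004	0.1
CLN2	0.1	0.3666666666666667	0.9	0.9	0.30000000000000004	0.1
MBF	0.1	0.5	0.9	0.9	0.1	0.1
SBF	0.1	0.5	0.9	0.9	0.1	0.1
CLB5	0.1	0.1	0.9	0.9	0.30000000000000004	0.1
CLB2	0.1	0.1	0.1	0.9	0.5	0.1
MCM1_SFF	0.1	0.1	0.1	0.9	0.7000000000000001	0.1
CDH1	0.9	0.6333333333333333	0.1	0.1	0.1	0.9
SIC1	0.9	0.7666666666666667	0.1	0.1	0.1	0.9
CDC20	0.1	0.1	0.1	0.1	0.9	0.1
CDC14	0.1	0.3666666666666667	0.1	0.1	0.1	0.1
SWI5	0.1	0.3666666666666667	0.1	0.1	0.30000000000000004	0.1
ESP1	0.1	0.3666666666666667	0.1	0.1	0.5	0.1
PDS1	0.9	0.7666666666666667	0.9	0.9	0.30000000000000004	0.9
SPO12	0.1	0.1	0.1	0.1	0.9	0.1
CDC5	0.1	0.1	0.1	0.1	0.9	0.1
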
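metric	S1	S2	S3	S4	S5	S6	S7	S8
reads	10662	8296	4784	2553	8328	7510	9125	6512
otus	217	228	137	55	135	218	179	214
shannon	2.37	2.47	2.07	1.97	1.91	2.52	2.45	2.36
simpson	0.86	0.89	0.81	0.79	0.82	0.90	0.89	0.86
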
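parameter	unit	limit	S1	S2	S3	S4	S5	S6	S7	S8	comparison
Ash	%		83.4	86.1	93.9	92.2	85.1	96.6	96.3	95.8	96.0
Dry mass	%		48.0	46.2	64.5	66.4	60.2	57.0	71.8	70.1	77.3
pH			6.75	6.81	7.26	7.17	3.95	7.05	7.28	7.32	7.20
C	%		16.60	13.90	6.11	7.83	14.90	3.42	3.72	4.22	3.96
N	%		1.18	1.07	1.02	0.68	0.73	0.62	0.56	0.68	0.28
P	%		0.91	0.60	0.50	0.71	0.22	0.78	0.63	0.53	0.46
S	%		0.01	0.02	0.01	0.08	0.02	0.01	0.01	<0.01	0.01
As	mg/kg		6.7	3.9	8.8	10.1	10.3	6.8	7.1	5.4	8.6
Be	mg/kg		0.83	0.69	1.34	4.44	0.79	0.73	0.63	0.63	1.02
Ca	%		1.74	4.65	1.97	0.74	0.32	1.36	1.77	2.57	5.21
Cd	mg/kg	1	<0.40	<0.40	<0.40	3.15	<0.40	<0.40	<0.40	<0.40	<0.40
Co	mg/kg		18.4	13.4	22.5	26.0	7.9	17.4	16.6	13.6	25.3
Cr	mg/kg	100	87.7	71.4	78.1	155.0	53.4	60.4	52.6	41.3	109
Cu	mg/kg	60	38.0	32.2	46.8	41.2	14.3	35.3	26.7	20.6	48.7
Hg	mg/kg	0.8	0.09	0.07	0.51	0.07	0.11	0.11	0.08	0.06	0.08
K	%		0.47	0.19	0.61	0.58	0.10	0.22	0.20	0.16	1.00
Mg	%		0.59	0.78	0.75	0.59	0.41	0.62	0.61	0.85	0.79
Na	%		0.02	0.02	0.01	0.03	0.01	0.01	0.01	0.01	0.02
Ni	mg/kg	50	79.3	63.7	91.7	85.0	30.8	69.2	60.5	48.0	130
Pb	mg/kg	85	24.7	24.9	19.5	46.3	35.4	25.5	20.0	16.4	11.8
V	mg/kg		55.0	42.1	87.3	282.0	87.6	57.0	48.1	48.8	78.3
Zn	mg/kg	200	256.0	84.6	111.0	162.0	59.4	117.0	95.8	79.5	97.9
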
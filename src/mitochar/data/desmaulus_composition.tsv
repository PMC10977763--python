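# Desmaulus extinctorium nucleotide composition by region, as published.
# The whole-mitogenome C% is printed as 11.72 in the table and 11.71 in the
# running text; the text value reproduces the published GC-skew of 0.214,
# the table value gives 0.213. Both are carried (mitogenome_text row).
region	size	a_pct	t_pct	g_pct	c_pct	at_pct	at_skew	gc_skew
mitogenome	16608	27.73	42.47	18.08	11.72	70.20	-0.210	0.213
mitogenome_text	16608	27.73	42.47	18.08	11.71	70.20	-0.210	0.214
COX1	1551	23.92	43.13	20.05	12.89	67.05	-0.287	0.217
COX2	693	27.13	38.96	20.49	13.42	66.09	-0.179	0.209
ATP8	159	27.67	44.65	15.72	11.95	72.32	-0.235	0.136
ATP6	696	23.13	46.70	16.67	13.51	69.83	-0.337	0.105
COX3	780	21.67	42.31	22.31	13.72	63.98	-0.323	0.238
NAD3	357	19.89	47.90	20.73	11.48	67.79	-0.413	0.287
NAD1	945	24.02	45.29	18.20	12.49	69.31	-0.307	0.186
NAD5	1872	26.82	42.63	16.61	13.94	69.45	-0.228	0.087
NAD4	1305	25.21	46.13	16.86	11.80	71.34	-0.293	0.176
NAD4L	303	26.73	43.89	19.80	9.57	70.62	-0.243	0.348
NAD6	504	26.39	46.43	18.65	8.53	72.82	-0.275	0.372
CYTB	1140	24.39	44.39	17.81	13.42	68.78	-0.291	0.140
NAD2	1089	25.34	46.37	18.64	9.64	71.71	-0.293	0.318
tRNAs	1485	34.61	35.62	17.24	12.53	70.23	-0.014	0.158
rRNAs	2260	34.91	38.14	17.08	9.87	73.05	-0.044	0.268
PCGs	11394	24.84	44.25	18.47	12.44	69.09	-0.281	0.195
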
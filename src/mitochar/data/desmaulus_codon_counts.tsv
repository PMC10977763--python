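# Desmaulus extinctorium mitogenome codon counts with published RSCU values
# (invertebrate mitochondrial code, translation table 5).
codon	aa	count	rscu_published
GCU	A	84	2.11
GCC	A	19	0.48
GCA	A	41	1.03
GCG	A	15	0.38
UGU	C	123	1.43
UGC	C	49	0.57
GAU	D	112	1.75
GAC	D	16	0.25
GAA	E	95	1.43
GAG	E	38	0.57
UUU	F	512	1.65
UUC	F	108	0.35
GGU	G	102	1.47
GGC	G	41	0.59
GGA	G	65	0.94
GGG	G	70	1.01
CAU	H	57	1.54
CAC	H	17	0.46
AUU	I	293	1.70
AUC	I	52	0.30
AAA	K	179	1.39
AAG	K	79	0.61
UUA	L	336	2.66
UUG	L	160	1.27
CUU	L	126	1.00
CUC	L	26	0.21
CUA	L	67	0.53
CUG	L	43	0.34
AUA	M	135	1.19
AUG	M	91	0.81
AAU	N	189	1.65
AAC	N	40	0.35
CCU	P	64	2.08
CCC	P	19	0.62
CCA	P	27	0.88
CCG	P	13	0.42
CAA	Q	53	1.15
CAG	Q	39	0.85
CGU	R	35	1.77
CGC	R	5	0.25
CGA	R	18	0.91
CGG	R	21	1.06
AGA	S	85	1.17
AGG	S	83	1.14
UCU	S	113	1.55
UCC	S	44	0.60
UCA	S	83	1.14
UCG	S	31	0.43
AGU	S	100	1.37
AGC	S	43	0.59
ACU	T	97	2.38
ACC	T	20	0.49
ACA	T	34	0.83
ACG	T	12	0.29
GUU	V	182	2.25
GUC	V	33	0.41
GUA	V	66	0.82
GUG	V	42	0.52
UGA	W	115	1.11
UGG	W	92	0.89
UAU	Y	240	1.56
UAC	Y	68	0.44
UAA	*	174	1.25
UAG	*	105	0.75
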
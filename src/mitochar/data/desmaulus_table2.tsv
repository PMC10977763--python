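# Desmaulus extinctorium mitogenome organization (GenBank OQ511529), genome_length=16608
gene	strand	start	end	length	start_codon	stop_codon	anticodon
COX1	H	1	1551	1551	ATT	TAA
COX2	H	1574	2266	693	ATG	TAA
tRNA-Asp	H	2313	2382	70			GTC
ATP8	H	2465	2623	159	ATG	TAA
ATP6	H	2681	3376	696	ATG	TAA
tRNA-Met	L	3403	3468	66			CAT
tRNA-Tyr	L	3477	3542	66			GTA
tRNA-Cys	L	3547	3612	66			GCA
tRNA-Trp	L	3613	3679	67			TCA
tRNA-Gln	L	3678	3743	66			TTG
tRNA-Gly	L	3748	3813	66			TCC
tRNA-Glu	L	3813	3882	70			TTC
12S rRNA	H	3963	4858	896
tRNA-Val	H	4858	4925	68			TAC
16S rRNA	H	4916	6279	1364
tRNA-Leu1	H	6293	6364	72			TAG
tRNA-Leu2	H	6369	6438	70			TAA
NAD1	H	6439	7383	945	ATG	TAA
tRNA-Pro	H	7396	7463	68			TGG
NAD6	H	7470	7973	504	ATG	TAA
Cytb	H	7990	9129	1140	ATG	TAA
tRNA-Ser2	H	9147	9212	66			TGA
NAD4l	H	9213	9515	303	ATG	TAG
NAD4	H	9596	10900	1305	ATG	TAA
tRNA-His	H	10911	10976	66			GTG
NAD5	H	10977	12848	1872	ATG	TAG
tRNA-Phe	H	12859	12924	66			GAA
tRNA-Thr	L	13573	13640	68			TGT
COX3	H	13745	14524	780	ATG	TAA
tRNA-Lys	H	14554	14628	75			TTT
tRNA-Ala	H	14684	14734	51			TGC
tRNA-Arg	H	14752	14821	70			TCG
tRNA-Asn	H	14843	14912	70			GTT
tRNA-Ile	H	14936	15005	70			GAT
NAD3	H	15010	15366	357	ATG	TAG
tRNA-Ser1	H	15416	15483	68			GCT
NAD2	H	15484	16572	1089	ATG	TAA
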
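# Ancestral gastropod signed gene order (circular; + = H strand).
# Reconstruction of the standard ancestral gastropod arrangement used as the
# comparison row in gene-rearrangement figures; printed sources give it only
# graphically, so this transcription is consistent with the three documented
# rearrangement events separating it from the Desmaulus extinctorium order.
COX1	+
COX2	+
trnD	+
ATP8	+
ATP6	+
trnF	-
NAD5	-
trnH	-
NAD4	-
NAD4L	-
trnT	+
trnS2	-
CYTB	-
NAD6	-
trnP	-
NAD1	-
trnL2	-
trnL1	-
rrnL	-
trnV	-
rrnS	-
COX3	+
trnE	+
trnG	+
trnQ	+
trnW	+
trnC	+
trnY	+
trnM	+
trnK	+
trnA	+
trnR	+
trnN	+
trnI	+
NAD3	+
trnS1	+
NAD2	+
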
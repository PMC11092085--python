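# Cohort 4q35 genotypes: long-read (ONT) calls vs optical genome mapping (OGM).
# ont_exact=0 means the ONT count is a lower bound (reported ">= n").
# accordance refers to pathogenetic status (a 4qA allele with <= 10 repeat units).
# OGM haplotype "unknown": the orthogonal assay could not resolve the haplotype.
sample	allele	ont_ru	ont_exact	ont_haplotype	ogm_ru	ogm_haplotype	accordance	mosaic
P1	1	2	1	A	2	A	Y	0
P1	2	19	0	B	27	B	Y	0
P2	1	2	1	A	2	A	Y	0
P2	2	12	0	B	28	B	Y	0
P3	1	2	1	A	2	A	Y	0
P3	2	14	0	B	28	B	Y	0
P4	1	2	1	A	2	A	Y	1
P4	2	31	0	A	37	A	Y	1
P4	3	18	1	B	18	B	Y	1
P5	1	4	1	A	4	A	Y	0
P5	2	12	1	A	12	A	Y	0
P6	1	4	1	A	4	A	Y	0
P6	2	11	0	A	12	A	Y	0
P7	1	4	1	A	4	A	Y	0
P7	2	12	1	A	12	A	Y	0
P8	1	6	1	A	6	A	Y	0
P8	2	13	0	A	29	A	Y	0
P9	1	6	1	A	6	A	Y	0
P9	2	15	0	B	21	B	Y	0
P10	1	7	1	A	7	A	Y	0
P10	2	11	0	A	26	A	Y	0
P11	1	7	1	A	7	A	Y	0
P11	2	7	1	B	7	B	Y	0
P12	1	8	1	A	8	A	Y	0
P12	2	16	0	B	17	B	Y	0
P13	1	8	1	A	8	A	Y	0
P13	2	20	0	B	24	B	Y	0
P14	1	9	1	A	9	A	Y	0
P14	2	15	1	B	15	B	Y	0
P15	1	9	1	A	9	A	Y	0
P15	2	15	0	B	24	B	Y	0
P16	1	9	1	A	9	A	Y	0
P16	2	20	0	A	24	A	Y	0
C1	1	12	1	A	12	A	Y	0
C1	2	13	0	B	17	B	Y	0
C2	1	10	0	A	12	A	Y	0
C2	2	17	1	B	17	B	Y	0
C3	1	14	1	A	14	A	Y	0
C3	2	14	0	A	17	A	Y	0
C4	1	14	1	A	14	A	Y	0
C4	2	18	1	A	17	A	Y	0
C5	1	11	0	A	17	A	Y	0
C5	2	21	0	B	18	B	Y	0
C6	1	21	1	A	21	A	Y	0
C6	2	18	1	B	18	B	Y	0
C7	1	11	0	A	24	A	Y	0
C7	2	12	0	B	27	B	Y	0
C8	1	16	0	A	28	A	Y	0
C8	2	14	0	B	14	B	Y	0
C9	1	18	0	A	33	A	Y	0
C9	2	12	0	B	32	B	Y	0
C10	1	27	0	A	34	A	Y	0
C10	2	17	0	B	26	B	Y	0
C11	1	13	1	B	13	B	Y	0
C11	2	13	0	B	29	B	Y	0
C12	1	15	0	B	16	B	Y	0
C12	2	15	0	B	16	B	Y	0
C13	1	20	1	B	20	B	Y	0
C13	2	18	0	B	22	unknown	Y	0
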
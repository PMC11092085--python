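# Cohort methylation levels (percent): long-read upstream/gene-body means and
# clone bisulfite sequencing (BSS) per-site values for 10 CpG sites in the most
# distal D4Z4 unit. Empty cells: assay not performed (insufficient DNA) or no
# 4qA allele present. ru_4qa is the repeat-unit annotation as printed.
sample	group	upstream	gene_body	bss	site1	site2	site3	site4	site5	site6	site7	site8	site9	site10	ru_4qa
P1	case	12.75	24.02	20.45	14.93	34.33	11.94	11.94	14.93	22.39	25.37	20.90	20.90	26.87	2
P2	case	17.56	26.92	33.80	20.00	48.00	12.00	40.00	20.00	56.00	62.00	32.00	26.00	22.00	2
P3	case	12.95	15.19	21.35	9.62	38.46	0.00	15.38	11.54	50.00	40.38	21.15	15.38	11.54	2
P4	case	65.03	67.99	59.18	44.90	67.35	38.78	75.51	44.90	75.51	63.27	71.43	48.98	65.31	2/37 (mosaic)
P5	case	27.76	35.27	26.83	11.11	33.33	7.94	20.63	23.81	41.27	39.69	33.33	23.81	33.33	4
P6	case	14.90	23.51	15.49	7.84	39.22	1.96	17.65	5.88	31.37	19.61	13.73	13.73	3.92	4
P7	case	31.11	37.57	30.38	11.54	48.08	5.77	38.46	9.62	65.38	46.15	26.92	38.46	13.46	4
P8	case	49.38	53.85											6
P9	case	47.73	57.86	38.25	24.56	71.93	10.53	36.84	24.56	56.14	45.61	45.61	38.60	28.07	6
P10	case	46.23	58.40	49.43	22.86	54.29	24.29	54.29	35.71	87.14	71.43	55.71	34.29	54.29	7
P11	case	27.13	35.02	35.00	19.23	34.62	0.00	26.92	9.62	71.15	73.08	51.92	44.23	19.23	7
P12	case	37.42	43.16											8
P13	case	43.79	56.12	41.09	28.30	60.38	16.98	33.96	32.08	69.81	54.72	0.00	28.30	45.28	8
P14	case	46.45	60.55	47.00	20.00	52.00	16.00	36.00	40.00	76.00	80.00	46.00	54.00	50.00	9
P15	case	29.56	44.94	39.61	25.49	64.71	5.88	27.45	35.29	58.82	72.55	54.90	25.49	25.49	9
P16	case	58.30	67.04	58.46	25.49	84.31	33.33	70.59	62.75	100.00	54.90	66.67	35.29	62.75	9
C1	control	47.25	59.72	48.01	16.98	73.58	20.75	56.60	45.28	83.02	73.58	0.00	24.53	37.74	12
C2	control	73.42	75.86	70.59	74.51	76.47	49.02	80.39	52.94	90.20	84.31	0.00	62.75	64.71	12
C3	control	62.14	71.98	58.80	14.00	82.00	24.00	72.00	54.00	94.00	78.00	56.00	48.00	66.00	14
C4	control	61.87	65.58	60.96	50.00	71.15	44.23	69.23	53.85	78.85	78.85	59.62	53.85	50.00	14
C5	control	61.39	69.25	49.62	13.46	40.38	11.54	59.62	67.31	96.15	69.23	40.38	46.15	51.92	17
C6	control	72.36	75.51	54.42	17.31	53.85	21.15	51.92	40.38	96.15	67.31	61.54	63.46	71.15	21
C7	control	70.44	78.23	68.04	70.59	78.43	13.73	68.63	68.63	90.20	90.20	76.47	74.51	49.02	24
C8	control	76.69	79.54	69.41	39.22	88.24	56.86	66.67	54.90	94.12	76.47	76.47	64.71	76.47	28
C9	control	72.48	75.97	70.94	41.51	86.79	32.08	79.25	71.70	100.00	84.91	71.70	62.26	79.25	33
C10	control	68.15	72.11	71.90	40.48	80.95	47.62	85.71	59.52	97.62	88.10	80.95	66.67	71.43	34
C11	control													Not 4qA
C12	control													Not 4qA
C13	control													Not 4qA
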
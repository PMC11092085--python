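# Allele-specific DUX4-upstream methylation (percent) for the five samples
# carrying both a pathogenetic and a non-pathogenetic 4qA allele, as printed
# in the study results (read-level analysis; P4 is the mosaic sample).
sample	ru	upstream_percent	pathogenetic
P4	2	12.15	1
P4	37	76.46	0
P5	4	11.91	1
P5	12	55.27	0
P8	6	23.54	1
P8	29	56.36	0
P10	7	32.39	1
P10	26	66.53	0
P16	9	33.19	1
P16	24	68.41	0
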
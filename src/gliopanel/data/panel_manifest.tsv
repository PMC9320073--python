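Target	Chromosome	Number of Amplicons	Covered Bases	% Overall Coverage	Number of Exons
ACVR1	chr2	23	1710	100	9
ATRX	chrX	106	8161	99	35
BRAF	chr7	42	2655	99	18
CDKN2A	chr9	11	1008	99	5
EGFR	chr7	63	4489	100	30
H3F3A	chr1	5	273	58	3
HIST1H3B	chr6	5	431	100	1
HIST1H3C	chr6	5	431	100	1
IDH1	chr2	20	1405	100	8
IDH2	chr15	20	1572	99	11
TP53	chr17	13	1503	100	12
PDGFRA	chr4	50	3710	100	22
PTEN	chr10	22	1901	98	10
TERT-Promoter	chr5	1	124	99	n/a
29 SNPs	chr1	30	30	100	n/a
25 SNPs	chr19	24	24	100	n/a
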
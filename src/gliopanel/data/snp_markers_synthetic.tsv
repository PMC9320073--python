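# Synthetic stand-in SNP markers: the real panel's marker identities/positions are unpublished.
marker_id	arm	chrom	pos
snp1p_01	1p	chr1	5000000
snp1p_02	1p	chr1	9000000
snp1p_03	1p	chr1	13000000
snp1p_04	1p	chr1	17000000
snp1p_05	1p	chr1	21000000
snp1p_06	1p	chr1	25000000
snp1p_07	1p	chr1	29000000
snp1p_08	1p	chr1	33000000
snp1p_09	1p	chr1	37000000
snp1p_10	1p	chr1	41000000
snp1p_11	1p	chr1	45000000
snp1p_12	1p	chr1	49000000
snp1p_13	1p	chr1	53000000
snp1p_14	1p	chr1	57000000
snp1p_15	1p	chr1	61000000
snp1p_16	1p	chr1	65000000
snp1p_17	1p	chr1	69000000
snp1p_18	1p	chr1	73000000
snp1p_19	1p	chr1	77000000
snp1p_20	1p	chr1	81000000
snp1p_21	1p	chr1	85000000
snp1p_22	1p	chr1	89000000
snp1p_23	1p	chr1	93000000
snp1p_24	1p	chr1	97000000
snp1p_25	1p	chr1	101000000
snp1p_26	1p	chr1	105000000
snp1p_27	1p	chr1	109000000
snp1p_28	1p	chr1	113000000
snp1p_29	1p	chr1	117000000
snp19q_01	19q	chr19	33000000
snp19q_02	19q	chr19	34000000
snp19q_03	19q	chr19	35000000
snp19q_04	19q	chr19	36000000
snp19q_05	19q	chr19	37000000
snp19q_06	19q	chr19	38000000
snp19q_07	19q	chr19	39000000
snp19q_08	19q	chr19	40000000
snp19q_09	19q	chr19	41000000
snp19q_10	19q	chr19	42000000
snp19q_11	19q	chr19	43000000
snp19q_12	19q	chr19	44000000
snp19q_13	19q	chr19	45000000
snp19q_14	19q	chr19	46000000
snp19q_15	19q	chr19	47000000
snp19q_16	19q	chr19	48000000
snp19q_17	19q	chr19	49000000
snp19q_18	19q	chr19	50000000
snp19q_19	19q	chr19	51000000
snp19q_20	19q	chr19	52000000
snp19q_21	19q	chr19	53000000
snp19q_22	19q	chr19	54000000
snp19q_23	19q	chr19	55000000
snp19q_24	19q	chr19	56000000
snp19q_25	19q	chr19	57000000
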
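sample_id	group	age	tumor_size_mm	pL	pV	pT	rete_testis	stage	total_rna_ug	rin
non_metastasized_1	non_metastasized	38	14	0	0	1	n	cSI	7.6	7.8
non_metastasized_2	non_metastasized	50	22	0	0	1	n	cSI	8.6	8.3
non_metastasized_3	non_metastasized	31	19	1	0	1	n	cSI	6.4	7.0
non_metastasized_4	non_metastasized	42	45	0	0	1	y	cSI	3.9	8.0
non_metastasized_5	non_metastasized	35	19	0	0	1	y	cSI	8.2	7.6
lymphogen_1	lymphogen	32	40	0	0	1	n	cSIIb	5.0	8.5
lymphogen_2	lymphogen	50	12	0	0	3	n	cSIIc	5.1	8.8
lymphogen_3	lymphogen	43	50	0	0	1	n	cSIIb	8.1	8.3
lymphogen_4	lymphogen	42	45	1	0	2	y	cSIIb	3.2	9.3
lymphogen_5	lymphogen	61	42	0	0	1	y	cSIIc	3.2	8.2
occult_1	occult	33	55	1	0	2	n	cSI	5.0	6.0
occult_2	occult	37	35	0	0	1	y	cSI	4.1	7.4
occult_3	occult	37	30	0	0	1	n	cSI	7.0	7.8
occult_4	occult	31	18	0	0	1	n	cSI	8.1	7.4
occult_5	occult	23	55	0	0	1	n	cSI	10.0	6.4
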
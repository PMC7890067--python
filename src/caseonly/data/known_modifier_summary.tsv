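variant_id	carrier_gene	snp_list	chrom	pos	nearest_gene	effect_allele	ref_allele	freq	r2	or_caseonly	p_caseonly	or_caseonly_erneg	p_caseonly_erneg	or_bcac	p_bcac	or_computed_printed	direction_printed	contrast_used	rounding_consistent
rs17426269	BRCA1	overall	1	88156923	.	A	G	0.16	1.00	0.90	2.70e-04	0.92	4.22e-02	1.05	1.70e-04	0.95	IOD	all	yes
rs13281615	BRCA1	overall	8	128355618	.	G	A	0.43	1.00	0.91	1.20e-05	0.94	4.14e-02	1.11	5.00e-28	1.01	TT1	all	yes
chr10_80841148_C_T	BRCA1	overall	10	80841148	ZMZ1	T	C	0.40	1.00	0.91	2.20e-06	0.91	1.01e-03	0.93	1.10e-14	0.84	ISD	all	no
chr16_52599188_C_T	BRCA1	overall	16	52599188	TOX3	T	C	0.29	1.00	0.85	1.80e-13	0.91	2.80e-03	1.23	7.00e-88	1.04	TT1	all	no
chr1_10566215_A_G	BRCA1	overall	1	10566215	PEX14	G	A	0.32	1.00	1.07	1.30e-03	1.12	1.10e-04	0.94	1.80e-09	1.05	TT1	er_negative	yes
rs17529111	BRCA1	overall	6	82128386	.	C	T	0.23	0.96	0.92	7.70e-04	0.86	1.96e-05	1.02	4.20e-02	0.88	IOD	er_negative	yes
rs66823261	BRCA1	er_negative	8	170692	RPL23AP53	C	T	0.23	0.92	.	.	0.88	2.37e-04	1.09	5.09e-09	0.96	TT1	er_negative	yes
rs62355902	BRCA2	overall	5	56053723	MAP3K1	T	A	0.18	0.98	0.89	1.10e-04	.	.	1.18	8.50e-42	1.05	TT1	all	yes
rs10759243	BRCA2	overall	9	110306115	RP11-438P9.2	A	C	0.31	1.00	0.89	4.60e-06	.	.	1.06	4.20e-10	0.95	TT1	all	no
chr22_40876234_C_T	BRCA2	overall	22	40876234	MKL1	C	T	0.11	1.00	0.88	2.80e-04	.	.	1.12	5.70e-16	0.98	TT1	all	no
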
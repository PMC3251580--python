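pathway	gene	n_snps	best_snp	snp_rank	maf	or	ci_low	ci_high	p
NAD1/NAD2	NMNAT3	36	rs7636269	1	0.48	1.12	1.05	1.20	0.0004
NAD2	ACP6	16	rs1344	1	0.41	1.11	1.04	1.18	0.0017
NAD1	QPRT	7	rs3862476	1	0.07	1.19	1.04	1.35	0.0087
NAD1/NAD2	NMNAT2	36	rs4652795	1	0.38	0.92	0.86	0.98	0.0099
NAD1/NAD2	NMNAT1	8	rs1220398	1	0.14	0.89	0.81	0.98	0.0169
NAD2	ITGB1BP3	8	rs2304191	1	0.11	1.11	1.01	1.23	0.0355
NAD2	ACPL2	31	rs3210458	2	0.09	1.12	1.00	1.25	0.0421
NAD2	NUDT12	5	rs371315	1	0.28	1.07	1.00	1.15	0.0686
NAD2	NT5C3L	6	rs9907244	1	0.43	0.95	0.89	1.01	0.1094
NAD1	NADSYN1	17	rs4945007	1	0.06	1.10	0.96	1.25	0.1555
NAD2	C9orf95	19	rs7021664	1	0.08	0.94	0.83	1.06	0.3193
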
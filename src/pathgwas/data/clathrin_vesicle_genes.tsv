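pathway	gene	n_snps	best_snp	snp_rank	maf	or	ci_low	ci_high	p
Clathrin/Lysosome/Retrograde	CLTA	10	rs10972786	1	0.06	1.27	1.11	1.45	0.0004
Clathrin/Lysosome	ARRB1	29	rs667791	1	0.39	1.11	1.04	1.19	0.0014
Clathrin/Lysosome/Retrograde	SH3GL2	92	rs2209426	1	0.17	0.87	0.80	0.95	0.0020
Clathrin/Lysosome/Retrograde	CLTC	10	rs7224631	1	0.09	1.19	1.06	1.32	0.0023
Clathrin/Lysosome	DNAJC6	38	rs1325607	1	0.21	1.12	1.03	1.21	0.0057
Clathrin/Lysosome	HSPA8	8	rs11218950	1	0.05	0.80	0.68	0.95	0.0087
Retrograde	NGF	45	rs12760036	1	0.10	0.85	0.76	0.96	0.0096
Clathrin/Lysosome	AP1G1	7	rs9932707	1	0.45	1.07	1.00	1.14	0.0353
Clathrin	VAMP2	3	rs3202848	1	0.37	0.93	0.86	1.00	0.0572
Clathrin	VAMP8	9	rs719023	1	0.39	0.94	0.88	1.00	0.0631
Retrograde	DNAL4	7	rs738141	1	0.17	1.08	1.00	1.18	0.0645
Clathrin	SNAP23	3	rs4924682	1	0.01	1.27	0.95	1.70	0.1087
Clathrin/Lysosome	DNM2	16	rs4804528	1	0.43	0.95	0.89	1.02	0.1437
Retrograde	DNM1	13	rs13285411	1	0.12	0.93	0.84	1.03	0.1463
Clathrin/Lysosome	AP1B1	14	rs5763140	1	0.11	1.08	0.97	1.19	0.1500
Clathrin/Lysosome	ARF1	4	rs3768331	1	0.38	1.05	0.98	1.12	0.1536
Clathrin	GBF1	15	rs1057050	1	0.06	0.90	0.78	1.04	0.1673
Retrograde	NTRK1	13	rs1888861	1	0.23	0.95	0.88	1.03	0.2275
Retrograde	AP2A2	12	rs7483870	1	0.23	0.96	0.89	1.04	0.3014
Retrograde	AP2A1	9	rs2286948	1	0.36	1.03	0.96	1.10	0.3694
Clathrin	STX4	1	rs10871454	1	0.39	1.00	0.94	1.07	0.9722
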
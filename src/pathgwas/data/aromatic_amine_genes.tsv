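gene	n_snps	best_snp	snp_rank	maf	or	ci_low	ci_high	p
UGT1A9	72	rs11892031	1	0.08	0.77	0.68	0.87	3.6e-5
NAT2	15	rs4646249	1	0.28	0.89	0.83	0.95	0.0013
NAT1	11	rs9650592	1	0.11	0.86	0.78	0.96	0.0054
UGT1A4	41	rs4148328	1	0.38	0.91	0.85	0.98	0.0086
UGT1A6	62	rs4148328	1	0.38	0.91	0.85	0.98	0.0086
NQO1	6	rs1437135	1	0.20	0.91	0.84	0.99	0.0275
CYP1B1	13	rs2855658	1	0.43	0.94	0.88	1.00	0.0477
CYP1A1	4	rs2472297	2	0.22	1.03	0.95	1.11	0.4758
CYP1A2	5	rs2472297	4	0.22	1.03	0.95	1.11	0.4758
SULT1A1	1	rs1968752	1	0.37	1.01	0.95	1.08	0.7321
SULT1A2	1	rs4788073	1	0.37	0.99	0.93	1.06	0.8344
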
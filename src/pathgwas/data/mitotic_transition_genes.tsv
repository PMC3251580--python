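gene	n_snps	best_snp	snp_rank	maf	or	ci_low	ci_high	p
FBXO5	11	rs9479476	1	0.11	0.83	0.75	0.93	0.0010
SMC3	8	rs7918064	1	0.27	0.90	0.84	0.97	0.0073
SPC24	18	rs4804149	2	0.28	0.92	0.85	0.99	0.0202
CENPQ	7	rs4267943	1	0.36	0.94	0.87	1.01	0.0706
NDC80	15	rs13381300	1	0.07	0.91	0.80	1.04	0.1673
NUP107	7	rs11177325	1	0.31	0.95	0.89	1.02	0.1951
CENPA	4	rs2060390	1	0.26	0.98	0.91	1.06	0.6106
SMC1A	2	rs1264013	1	0.42	1.00	0.95	1.05	0.9876
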
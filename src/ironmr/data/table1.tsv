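# 12-SNP instrument table for the four systemic iron-status biomarkers
# (ferritin, iron, transferrin, transferrin saturation) against heart failure
# in UK Biobank (Neale-lab GWAS of 361,194 individuals).
# Exposure effects are per-allele SD-unit associations from the Iron Status
# Genetics Consortium meta-analysis (n = 48,972 Europeans).
# NOTE other_allele is fixture metadata: the source table prints only the
# effect allele, so conventional non-palindromic other-alleles were supplied
# here for these 12 well-known variants (synthetic metadata, not source data).
# f_reported is the instrument-strength F statistic as printed in the source
# table; it is not reproduced by (beta/se)^2 on the printed inputs and is
# carried for reference only.
biomarker	snp_id	gene	chrom	pos	effect_allele	other_allele	eaf	f_reported	beta_exp	se_exp	p_exp	beta_out	se_out	p_out
ferritin	rs1800562	HFE	6	26093141	A	G	0.067	256	0.204	0.016	1.54e-38	-1.74e-04	0.00027	0.515
ferritin	rs1799945	HFE	6	26091179	C	T	0.85	53	-0.065	0.01	1.71e-10	1.32e-04	0.0002	0.511
ferritin	rs855791	TMPRSS6	22	37462936	A	G	0.446	73	-0.055	0.007	1.38e-14	-1.02e-04	0.00015	0.486
ferritin	rs744653	WDR75-SLC40A1	2	190000000	T	C	0.854	97	-0.089	0.01	8.37e-19	1.35e-04	0.00021	0.516
ferritin	rs651007	ABO	9	136000000	T	C	0.202	40	-0.05	0.009	1.31e-08	5.88e-04	0.00018	0.001
ferritin	rs411988	TEX14	17	56709034	A	G	0.564	47	-0.044	0.007	1.59e-10	1.95e-04	0.00015	0.178
iron	rs1800562	HFE	6	26093141	A	G	0.067	668	0.328	0.016	2.72e-97	-1.74e-04	0.00027	0.515
iron	rs1799945	HFE	6	26091179	C	T	0.85	450	-0.189	0.01	1.10e-81	1.32e-04	0.0002	0.511
iron	rs855791	TMPRSS6	22	37462936	A	G	0.446	806	-0.181	0.007	1.32e-139	-1.02e-04	0.00015	0.486
iron	rs8177240	TF	3	133000000	T	G	0.669	95	-0.066	0.007	6.65e-20	-9.63e-05	0.00015	0.526
iron	rs7385804	TFR2	7	100000000	A	C	0.621	95	0.064	0.007	1.36e-18	-9.27e-05	0.00015	0.533
transferrin	rs1800562	HFE	6	26093141	A	G	0.067	1446	-0.479	0.016	8.90e-196	-1.74e-04	0.00027	0.515
transferrin	rs1799945	HFE	6	26091179	C	T	0.85	163	0.114	0.01	9.36e-30	1.32e-04	0.0002	0.511
transferrin	rs855791	TMPRSS6	22	37462936	A	G	0.446	47	0.044	0.007	1.98e-09	-1.02e-04	0.00015	0.486
transferrin	rs744653	WDR75-SLC40A1	2	190000000	T	C	0.854	57	0.068	0.01	1.35e-11	1.35e-04	0.00021	0.516
transferrin	rs8177240	TF	3	133000000	T	G	0.669	3346	-0.38	0.007	8.43e-610	-9.63e-05	0.00015	0.526
transferrin	rs9990333	TFRC	3	196000000	T	C	0.46	63	-0.051	0.007	1.95e-13	-6.56e-05	0.00014	0.651
transferrin	rs4921915	NAT2	8	18272466	A	G	0.782	104	0.079	0.009	7.05e-19	-8.05e-05	0.00017	0.643
transferrin	rs6486121	ARNTL	11	13355770	T	C	0.631	48	-0.046	0.007	3.89e-10	-2.03e-04	0.00015	0.176
transferrin	rs174577	FADS2	11	61604814	A	C	0.33	83	0.062	0.007	2.28e-17	1.45e-04	0.00015	0.338
ts	rs1800562	HFE	6	26093141	A	G	0.067	2127	0.577	0.016	2.19e-270	-1.74e-04	0.00027	0.515
ts	rs1799945	HFE	6	26091179	C	T	0.85	676	-0.231	0.01	5.13e-109	1.32e-04	0.0002	0.511
ts	rs855791	TMPRSS6	22	37462936	A	G	0.446	889	-0.19	0.008	6.41e-137	-1.02e-04	0.00015	0.486
ts	rs8177240	TF	3	133000000	T	G	0.669	218	0.1	0.008	7.24e-38	-9.63e-05	0.00015	0.526
ts	rs7385804	TFR2	7	100000000	A	C	0.621	67	0.054	0.008	6.07e-12	-9.27e-05	0.00015	0.533
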
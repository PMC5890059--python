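snp_id	gene	risk_allele_iron	risk_allele_ferritin	risk_allele_transferrin	risk_allele_tsat	beta_iron	beta_ferritin	beta_transferrin	beta_tsat	genotyped
rs1799945	HFE	C	C	C	C	-0.189	-0.065	0.114	-0.231	0
rs1800562	HFE	G	G	G	G	-0.328	-0.204	0.479	-0.577	1
rs855791	TMPRSS6	A	A	A	A	-0.181	-0.055	0.044	-0.190	1
rs8177240	TF	T		G	G	-0.066		0.380	-0.100	0
rs7385804	TFR2	C			C	-0.064			-0.054	0
rs744653	WDR75-SLC40A1		T	T			-0.089	0.068		1
rs651007	ABO		T				-0.050			0
rs411988	TEX14		A				-0.044			0
rs9990333	TFRC			C				0.051		1
rs4921915	NAT2			A				0.079		0
rs6486121	ARNTL			C				0.046		1
rs174577	FADS2			A				0.062		0
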
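TRAIT_LABEL	CHR	POS	ID	CONSEQUENCE	A1	A2	A1FREQ	BETA	SE	P	LOCUS	NOVEL	MAGMA_P
PDFF (WFM)	1	110232983	rs140584594	missense_variant	A	G	0.267	-0.049	0.007	1.42E-13	GSTM1	1	
PDFF (BMI)	1	172323134	rs17277932	intron_variant	A	G	0.145	0.049	0.008	5.91E-09	DNM3	1	
PDFF (VAT)	1	220970028	rs2642438	missense_variant	A	G	0.296	-0.061	0.006	7.89E-24	MARC1	0	5.91E-14
PDFF (BMI)	2	27730940	rs1260326	missense_variant	T	C	0.392	0.063	0.006	4.23E-25	GCKR	0	4.51E-14
PDFF (WFM)	2	165501927	rs5835988	intergenic_variant	TG	T	0.408	-0.046	0.006	3.25E-14	COBLL1	0	3.58E-11
PDFF (WFM)	2	227100579	2:227100579_TC_T	intergenic_variant	TC	T	0.348	-0.042	0.006	1.63E-11	IRS1	0	
PDFF (WFM)	3	12393125	rs1801282	missense_variant	G	C	0.122	-0.059	0.009	6.61E-11	PPARG	0	
PDFF (WFM)	3	25484121	rs79905393	intron_variant	A	G	0.036	-0.094	0.016	2.86E-09	RARB	1	
PDFF (WFM)	3	150066540	rs62271373	regulatory_region_variant	A	T	0.060	0.082	0.013	1.02E-10	TSC22D2	1	
PDFF	4	100239319	rs1229984	missense_variant	T	C	0.024	-0.165	0.023	1.26E-12	ADH1B	0	
PDFF (VAT)	4	100503761	rs11937107	intron_variant	T	C	0.252	-0.044	0.006	4.87E-12	MTTP	0	8.20E-12
PDFF (BMI)	4	100562374	rs36029295	intron_variant	GA	G	0.039	0.085	0.015	2.68E-08	RP11-766F14.2	1	
PDFF (VAT)	5	55808342	rs392794	intron_variant	C	T	0.254	-0.063	0.006	5.09E-23	AC022431.2	0	6.83E-13
PDFF (BMI)	5	72951153	5:72951153_GT_G	intron_variant	G	GT	0.462	0.033	0.006	3.45E-08	ARHGEF28	1	
PDFF (BMI)	6	26093141	rs1800562	missense_variant	A	G	0.077	0.062	0.011	3.27E-08	HFE	0	
PDFF (BMI)	7	28172732	rs702814	intron_variant	C	T	0.492	0.035	0.006	3.73E-09	JAZF1	0	
PDFF (VAT)	7	65431686	rs6955582	intron_variant	A	G	0.451	-0.034	0.006	1.72E-09	GUSB	1	1.03E-08
PDFF (VAT)	8	25464670	rs73221948	intergenic_variant	T	G	0.294	0.046	0.006	3.05E-13	CDCA2	1	
PDFF (BMI)	8	126500031	rs28601761	intron_variant	G	C	0.420	-0.072	0.006	1.63E-32	TRIB1	0	4.72E-07
PDFF (VAT)	9	132566666	rs7029757	non_coding_transcript_exon_variant	A	G	0.096	-0.063	0.009	3.15E-11	TOR1B	0	
PDFF (VAT)	10	113910721	rs1129555	3_prime_UTR_variant	A	G	0.273	0.062	0.006	2.52E-23	GPAM	0	4.04E-14
PDFF (VAT)	10	114024573	10:114024573_GA_G	intergenic_variant	G	GA	0.286	-0.039	0.006	2.24E-10	TECTB	1	4.90E-09
PDFF (WFM)	11	823586	rs140201358	missense_variant	G	C	0.015	0.147	0.025	2.35E-09	PNPLA2	0	
PDFF (VAT)	11	75456134	rs531117	downstream_gene_variant	T	C	0.157	-0.042	0.008	3.91E-08	MOGAT2	1	
PDFF	12	3685100	rs1985912	intron_variant	G	A	0.326	-0.043	0.008	2.67E-08	PRMT8	1	
PDFF (WFM)	12	124476873	rs12833624	intron_variant	T	C	0.337	-0.039	0.006	3.37E-10	FAM101A	1	1.01E-06
PDFF (VAT)	17	7116853	rs446994	intron_variant	C	A	0.422	0.033	0.006	3.43E-09	DLG4	1	1.04E-08
PDFF	17	17974014	rs11439486	downstream_gene_variant	T	TA	0.330	0.046	0.008	7.63E-09	GID4	0	2.19E-07
PDFF (VAT)	17	64210580	rs1801689	missense_variant	C	A	0.029	0.099	0.016	1.63E-09	APOH	1	
PDFF (NA)	19	18229208	rs56252442	intron_variant	T	G	0.253	0.048	0.008	5.11E-09	MAST3	0	5.13E-07
PDFF (VAT)	19	19379549	rs58542926	missense_variant	T	C	0.075	0.292	0.011	4.7E-168	TM6SF2	0	5.00E-10
PDFF (VAT)	19	33834096	rs73026242	downstream_gene_variant	G	A	0.072	0.060	0.011	3.59E-08	CEBPG	1	
PDFF (BMI)	19	45411941	rs429358	missense_variant	C	T	0.151	-0.102	0.008	2.92E-35	APOE	0	1.67E-15
PDFF	19	45830763	rs344790	upstream_gene_variant	A	C	0.421	0.043	0.007	2.68E-09	CKM	1	
PDFF (VAT)	19	54671421	rs60204587	intron_variant	A	G	0.426	0.045	0.006	1.42E-15	MBOAT7	0	5.27E-15
PDFF (WFM)	20	39142516	rs2207132	intergenic_variant	A	G	0.034	0.092	0.016	1.73E-08	MAFB	1	
PDFF (VAT)	22	44324730	rs738408	synonymous_variant	T	C	0.214	0.237	0.007	1.7E-269	PNPLA3	0	1.38E-14
cT1 (BMI)	1	15810346	rs12130283	intron_variant	C	T	0.484	0.045	0.007	5.33E-10	CELA2B	1	6.91E-08
cT1 (BMI)	1	220100497	rs759359281	splice_polypyrimidine_tract_variant	C	CA	0.055	0.129	0.016	4.74E-15	SLC30A10	0	
cT1 (VAT)	4	103188709	rs13107325	missense_variant	T	C	0.070	0.556	0.015	< 4.94E-324	SLC39A8	0	2.01E-18
cT1 (VAT)	6	25878848	rs55925606	intron_variant	G	A	0.073	-0.149	0.015	1.07E-24	SLC17A3	0	3.32E-09
cT1 (VAT)	8	9173209	rs7012637	intron_variant	A	G	0.472	0.043	0.007	9.39E-09	RP11-10A14.4	1	
cT1 (BMI)	8	18272881	rs1495741	regulatory_region_variant	G	A	0.219	-0.064	0.009	4.5E-13	NAT2	1	
cT1 (NA)	9	136149830	rs532436	intron_variant	A	G	0.183	0.079	0.010	7.47E-15	ABO	1	
cT1 (WFM)	10	113921825	rs2792735	intron_variant	G	A	0.277	0.046	0.008	4.05E-08	GPAM	0	4.81E-07
cT1 VAT)	11	61549025	rs174533	intron_variant	A	G	0.351	0.052	0.008	2.49E-11	MYRF	1	3.51E-07
cT1 (NA)	12	51511269	rs59372312	intron_variant	G	A	0.067	-0.088	0.016	2.33E-08	TFCP2	1	
cT1 (BMI)	14	24572932	rs111723834	missense_variant	A	G	0.016	0.383	0.029	1.7E-39	PCK2	0	9.99E-08
cT1 (VAT)	16	77423427	rs2454933	intron_variant	T	C	0.082	0.075	0.014	3.69E-08	ADAMTS18	1	
cT1 (NA)	18	59323966	18:59323966_CTT_C	intron_variant	C	CTT	0.287	-0.050	0.009	1.28E-08	CDH20	1	
cT1 (WFM)	19	19379549	rs58542926	missense_variant	T	C	0.074	0.141	0.014	4.22E-23	TM6SF2	0	4.46E-07
cT1 (VAT)	19	33890838	rs10406327	intron_variant	G	C	0.477	-0.042	0.007	1.24E-08	PEPD	1	1.84E-06
cT1 (BMI)	19	49206172	rs516246	intron_variant	C	T	0.489	-0.053	0.007	3.67E-13	FUT2	0	1.00E-13
cT1 (VAT)	22	37469192	rs6000553	intron_variant	A	G	0.466	0.070	0.007	7.53E-21	TMPRSS6	0	4.81E-12
cT1 (BMI)	22	44324727	rs738409	missense_variant	G	C	0.214	0.120	0.009	3.2E-41	PNPLA3	0	2.85E-13
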
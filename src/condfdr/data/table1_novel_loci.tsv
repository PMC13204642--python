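subtype	snp_id	chrom	pos	func	ref_allele	effect_allele	z	p	condfdr	containing_gene	mapped_genes
DLBCL	rs11582702	1	160727986	intergenic	C	T	-4.57	6.09e-6	0.007251		SLAMF7
DLBCL	rs9885976	6	16940672	intergenic	C	T	-4.59	5.50e-6	0.005573
DLBCL	rs2251301	8	11119037	ncRNA_intronic	C	T	-4.93	1.05e-6	0.009425		FAM167A
DLBCL	rs117408955	13	112538767	intergenic	G	A	-4.32	1.85e-5	0.008798
FL	rs10189015	2	111918472	intronic	G	A	5.256825	2.31e-7	0.001103	BCL2L11	BCL2L11,ACOXL
FL	rs2681416	3	121817613	intronic	G	A	5.425597	9.36e-8	0.000638	CD86	CD86
CLL	rs12021613	1	20961950	intronic	C	T	-4.86479	1.95e-6	0.002663	PINK1	PINK1,CDA,DDOST
CLL	rs17862882	2	234682496	downstream	C	A	4.358045	2.02e-5	0.008728		UGT1A1,UGT1A3,UGT1A4,UGT1A5,UGT1A6,UGT1A7,UGT1A8,UGT1A9,UGT1A10,MROH2A
CLL	rs1274963	3	39191029	intronic	A	G	-4.8292	1.56e-6	0.006201	CSRNP1	CSRNP1
CLL	rs2242652	5	1280028	intronic	G	A	5.323386	1.92e-7	0.000275	TERT	TERT
CLL	rs56703405	5	78186110	intronic	T	G	4.626346	6.03e-6	0.006574	ARSB	ARSB
CLL	rs75320317	6	7202278	intronic	T	C	-4.49139	7.90e-6	0.008553	RREB1	RREB1
CLL	rs10946876	6	26896889	intronic	G	A	4.912766	1.54e-6	0.001625
CLL	rs67063178	16	82893008	UTR3	C	T	-4.89011	1.15e-6	0.00518	CDH13	CDH13
CLL	rs1915033	16	85985431	intergenic	T	C	5.055625	7.60e-7	0.000396
CLL	rs139818184	17	37514738	intronic	C	A	-4.57152	7.76e-6	0.00498	FBXL20	FBXL20
CLL	rs7217237	17	38827062	intergenic	A	C	-4.5853	7.28e-6	0.005523		SMARCE1,KRT222,KRT24
CLL	rs55941736	19	48831886	intronic	A	G	-5.46051	5.58e-8	0.000587	EMP3	EMP3,ODAD1,TMEM143
CLL	rs76473307	20	57406068	ncRNA_intronic	A	C	-5.32251	1.93e-7	0.000483		GNAS
MZL	rs181136801	2	71705498	intronic	T	C	5.154366	3.05e-7	0.003532	DYSF	DYSF
MZL	rs1202393	7	149000000	intronic	G	A	4.492213	7.80e-6	0.009952	ZNF282	ZNF282,ZNF398
MZL	rs80081219	11	71524587	ncRNA_exonic		T	4.462791	9.29e-6	0.006537		DEFB108B,NUMA1,RNF121,IL18BP,XNDC1N
MZL	rs1123007	11	71185357	intronic	G	A	4.510585	7.16e-6	0.004986	NADSYN1	NADSYN1,DHCR7
MZL	rs575280	11	116527728	ncRNA_intronic	A	G	4.421853	1.12e-5	0.006556
MZL	rs34893450	16	54995307	intergenic	G	A	4.967814	8.02e-7	0.007275
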
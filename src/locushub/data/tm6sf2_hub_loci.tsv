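locus_id	chrom	gwas_flag	member_snps	gene_labels
TM6SF2	19	1	rs201189528	TM6SF2
SUGP1	19	0		SUGP1
LPP	3	0		LPP
KCNIP3	2	0		KCNIP3
CTRB1/BCAR1	16	1	rs7202844	CTRB1,BCAR1
CELSR2/PSRC1	1	1	rs599839	CELSR2,PSRC1
SORT1	1	0		SORT1
NOTCH2	1	0		NOTCH2
BCAR3	1	0		BCAR3
21q22.3	21	0		DNMT3L,B3GALT5,ABCG1
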
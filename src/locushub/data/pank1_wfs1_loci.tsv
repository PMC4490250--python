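locus_id	chrom	gwas_flag	member_snps	gene_labels
PANK1	10	1	rs10160034	PANK1
WFS1	4	1	rs1801214	WFS1
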
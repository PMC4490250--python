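locus_id	chrom	gwas_flag	member_snps	gene_labels
IGF2BP2	3	1	rs16860235	IGF2BP2
HNF1A	12	1	rs1169288	HNF1A
GRM5	11	0		GRM5
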
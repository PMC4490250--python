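locus_u	locus_v	layer	evidence
IGF2BP2	GRM5	spatial	ENCODE
HNF1A	GRM5	spatial	ENCODE
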
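locus_u	locus_v	layer	evidence
PANK1	WFS1	spatial	ENCODE
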
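locus_u	locus_v	layer	evidence
TM6SF2	SUGP1	spatial	ENCODE
TM6SF2	LPP	spatial	ENCODE
TM6SF2	KCNIP3	spatial	ENCODE
KCNIP3	CTRB1/BCAR1	spatial	ENCODE
CELSR2/PSRC1	SORT1	spatial	ENCODE
CELSR2/PSRC1	NOTCH2	spatial	ENCODE
CELSR2/PSRC1	BCAR3	spatial	ENCODE
CELSR2/PSRC1	21q22.3	spatial	ENCODE
CTRB1/BCAR1	BCAR3	functional	protein_interaction_C_terminal
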
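gene	alteration_type	alteration	level
BRCA1	mutation	any	1
BRCA2	mutation	any	1
PIK3CA	mutation	H1047R	3a
PIK3CA	mutation	E545K	3a
AKT1	mutation	E17K	3a
ERBB2	mutation	any	3a
ERBB2	amplification	any	3b
PTEN	mutation	any	4
PTEN	deletion	any	4
ESR1	mutation	any	3a
NTRK1	fusion	any	1
NTRK3	fusion	any	1
FGFR2	fusion	any	3a
FGFR1	amplification	any	4
KRAS	mutation	G12C	2
MTOR	mutation	any	4
NF1	mutation	any	4
CDKN2A	deletion	any	4
MDM2	amplification	any	3b
TSC1	mutation	any	3a
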
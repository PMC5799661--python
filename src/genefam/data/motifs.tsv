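# Representative plant cis-regulatory element consensi (IUPAC), editable.
name	consensus	both_strands
G-box	CACGTG	True
E-box	CANNTG	True
ABRE	ACGTG	True
MBS	CAACTG	True
MRE	AACCTAA	True
HSE	AAAAAATTTC	True
LTR	CCGAAA	True
CRT/DRE	RCCGAC	True
P-box	CCTTTTG	True
TATC-box	TATCCCA	True
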
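ANTIGEN_PRESENTATION	immune pathway	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	PSMB8	PSMB9
TCR_SIGNALING	immune pathway	CD3D	CD3E	CD3G	CD2	LCK	ZAP70	LAT	TRAT1
BCR_SIGNALING	immune pathway	CD79A	CD79B	CD19	BANK1	BLK	SYK
IFN_GAMMA_RESPONSE	immune pathway	STAT1	IRF1	CXCL9	CXCL10	GBP1	IDO1
CYTOTOXICITY	immune pathway	GZMA	GZMB	PRF1	GNLY	KLRD1	NKG7
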
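B_lineage	cell-type markers	CD79A	CD79B	MS4A1	CD19	BANK1
T_cells	cell-type markers	CD3D	CD3E	CD3G	CD2	TRAT1
CD8_T_cells	cell-type markers	CD8A	CD8B
Cytotoxic_lymphocytes	cell-type markers	GZMA	GZMB	PRF1	GNLY	KLRD1
NK_cells	cell-type markers	NCR1	KLRC1	NKG7	NCR3
Monocytic_lineage	cell-type markers	CD14	CD163	CSF1R	ITGAM
Myeloid_dendritic	cell-type markers	CD1C	CLEC10A	FCER1A
Neutrophils	cell-type markers	FCGR3B	CSF3R	S100A8
Endothelial	cell-type markers	PECAM1	VWF	CDH5
Fibroblasts	cell-type markers	COL1A1	COL3A1	ACTA2	PDGFRB
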
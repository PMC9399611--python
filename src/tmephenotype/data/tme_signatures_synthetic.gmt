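Activated CD4 T cell	TME-cell	CD4	IL2RA	CD69	TNFRSF9	ICOS	CD40LG	IL2	TNF	BATF	CCR7
Activated CD8 T cell	TME-cell	CD8A	CD8B	GZMB	PRF1	IFNG	GZMK	KLRG1	ZAP70	CD3D	CD3E
Activated B cell	TME-cell	CD19	MS4A1	CD79A	CD79B	CD86	TNFRSF13B	CD27	IGHM	BLK	CR2
Central memory CD4 T cell	TME-cell	CCR7	SELL	IL7R	TCF7	LEF1	CD28	CD27	FOXP1	BCL2	MAL
Central memory CD8 T cell	TME-cell	CCR7	SELL	IL7R	CD8A	TCF7	LEF1	EOMES	CD27	GZMK	NELL2
Effector memory CD4 T cell	TME-cell	CCR5	CXCR3	IL7R	GZMA	KLRB1	CD40LG	PRDM1	FAS	S100A4	ANXA1
Effector memory CD8 T cell	TME-cell	GZMA	GZMH	KLRD1	CX3CR1	FGFBP2	GNLY	NKG7	TBX21	FCGR3A	ZEB2
Gamma delta T cell	TME-cell	TRDC	TRGC1	TRGC2	KLRC1	KLRD1	NKG7	CD3D	TRDV1	TRDV2	CD160
Immature B cell	TME-cell	CD19	MS4A1	CD38	IGHD	TCL1A	VPREB3	CD24	CD72	PAX5	CD9
Memory B cell	TME-cell	CD27	MS4A1	CD19	TNFRSF13B	AIM2	CD80	SPIB	BANK1	CD40	FCRL4
Regulatory T cell	TME-cell	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18	CCR8	TNFRSF4	LRRC32	IL10	ENTPD1
T follicular helper cell	TME-cell	CXCR5	BCL6	ICOS	PDCD1	IL21	CD200	SH2D1A	MAF	TOX2	BTLA
Type 1 T helper cell	TME-cell	TBX21	IFNG	IL12RB2	CXCR3	STAT4	IL18R1	CCR5	HAVCR2	IL2	LTA
Type 2 T helper cell	TME-cell	GATA3	IL4	IL5	IL13	CCR4	IL4R	STAT6	PTGDR2	IL9	CCR8
Type 17 T helper cell	TME-cell	RORC	IL17A	IL17F	IL22	CCR6	IL23R	STAT3	IL21	KLRB1	CTSH
Activated dendritic cell	TME-cell	CD83	CCR7	LAMP3	CD80	CD86	CD40	IDO1	EBI3	IL12B	FSCN1
Plasmacytoid dendritic cell	TME-cell	CLEC4C	IL3RA	LILRA4	IRF7	TCF4	GZMB	JCHAIN	PLD4	SERPINF1	ITM2C
Immature dendritic cell	TME-cell	CD1A	CD1C	FCER1A	CLEC10A	ITGAX	CSF1R	CD209	MRC1	CLEC4A	VDR
Macrophage M1	TME-cell	NOS2	IL1B	IL6	TNF	CXCL9	CXCL10	CXCL11	SOCS1	IRF5	PTGS2
Macrophage M2	TME-cell	CD163	MRC1	MSR1	IL10	CCL22	CD209	TGFB1	ARG1	CCL17	STAB1
Natural killer cell	TME-cell	NCR1	KLRD1	NKG7	GNLY	KIR2DL1	KIR2DL3	NCAM1	PRF1	KLRK1	FCGR3A
Natural killer T cell	TME-cell	CD3D	NCAM1	KLRB1	ZBTB16	IL2RB	GZMA	CD244	SLAMF6	VA24	DPP4
CD56bright natural killer cell	TME-cell	NCAM1	SELL	XCL1	XCL2	KLRC1	GZMK	IL7R	CD44	TNFSF10	KIT
CD56dim natural killer cell	TME-cell	FCGR3A	FGFBP2	GZMB	PRF1	CX3CR1	KIR2DL1	KIR3DL1	SPON2	GNLY	S1PR5
MDSC	TME-cell	ITGAM	CD33	ARG1	S100A8	S100A9	OLR1	IL4R	STAT3	NOS2	CYBB
Mast cell	TME-cell	TPSAB1	TPSB2	CPA3	MS4A2	KIT	CMA1	HDC	GATA2	SLC18A2	HPGDS
Monocyte	TME-cell	CD14	FCN1	S100A12	VCAN	LYZ	CSF1R	CCR2	FCGR1A	ITGAM	CD36
Neutrophil	TME-cell	FCGR3B	CSF3R	CXCR2	FPR1	SELPLG	MPO	ELANE	S100A8	CEACAM8	CXCR1
Eosinophil	TME-cell	SIGLEC8	IL5RA	CCR3	PRG2	EPX	RNASE2	RNASE3	GATA1	HRH4	ADORA3
Fibroblast	TME-cell	COL1A1	COL1A2	COL3A1	ACTA2	FAP	PDGFRB	THY1	DCN	LUM	POSTN
Endothelial cell	TME-cell	PECAM1	VWF	CDH5	CLDN5	PLVAP	KDR	TEK	ENG	ESM1	EGFL7
ESTIMATE immune	estimate-immune	PTPRC	CD3D	CD3E	CD2	CD52	LAPTM5	CXCR4	CCL5	IL7R	LTB	CD48	CORO1A	SASH3	GZMA	ARHGAP15	EVI2B	NKG7	CD53	TRBC2	ITGAL
ESTIMATE stromal	estimate-stromal	COL1A1	COL1A2	COL3A1	COL5A1	COL6A3	DCN	LUM	FBLN1	FBN1	MMP2	SPARC	THBS2	VCAN	PDGFRB	FAP	POSTN	ACTA2	TAGLN	CALD1	AEBP1
Exhausted T cell	exhaustion	PDCD1	CTLA4	HAVCR2	LAG3	TIGIT	TOX	ENTPD1	CXCL13	LAYN	BATF
Cytolytic activity	cytolytic	GZMA	PRF1
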
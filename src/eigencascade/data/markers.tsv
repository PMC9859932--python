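symbol	category	note
SLA1A2	glia	literature-curated CNS marker
VIM	glia	literature-curated CNS marker
AQP4	glia	literature-curated CNS marker
GFAP	astrocytes	literature-curated CNS marker
S100B	astrocytes	literature-curated CNS marker
SLC1A3	astrocytes	literature-curated CNS marker
ALDH1L1	astrocytes	literature-curated CNS marker
BYSL	astrocytes	literature-curated CNS marker
GJA1	astrocytes	literature-curated CNS marker
GLUL	astrocytes	literature-curated CNS marker
PYGB	astrocytes	literature-curated CNS marker
OLIG2	oligodendrocytes	literature-curated CNS marker
CNP	oligodendrocytes	literature-curated CNS marker
CA2	oligodendrocytes	literature-curated CNS marker
NFIA	oligodendrocytes	literature-curated CNS marker
NFIB	oligodendrocytes	literature-curated CNS marker
PDGFRA	OPCs	literature-curated CNS marker
SPP1	microglia	literature-curated CNS marker
TMEM119	microglia	literature-curated CNS marker
ITGAM	microglia	literature-curated CNS marker
PTPRC	microglia	literature-curated CNS marker
AIF1	microglia	literature-curated CNS marker
RBFOX3	neurons	literature-curated CNS marker
TBR1	neurons	literature-curated CNS marker
SOX5	neurons	literature-curated CNS marker
DCX	neurons	literature-curated CNS marker
BCL11B	neurons	literature-curated CNS marker
FEZF2	neurons	literature-curated CNS marker
SATB2	neurons	literature-curated CNS marker
CUX1	neurons	literature-curated CNS marker
CUX2	neurons	literature-curated CNS marker
POU3F2	neurons	literature-curated CNS marker
POU3F3	neurons	literature-curated CNS marker
TUBB3	neurons	literature-curated CNS marker
NEUROD1	excitatory neurons	literature-curated CNS marker
NEUROD2	excitatory neurons	literature-curated CNS marker
NEUROD6	excitatory neurons	literature-curated CNS marker
GRIN2B	excitatory neurons	literature-curated CNS marker
CALB2	CGE	literature-curated CNS marker
RELN	CGE	literature-curated CNS marker
NR2F1	CGE	literature-curated CNS marker
NR2F2	CGE	literature-curated CNS marker
VIP	CGE	literature-curated CNS marker
SIX3	LGE	literature-curated CNS marker
ISL1	LGE	literature-curated CNS marker
EBF1	LGE	literature-curated CNS marker
LHX6	MGE	literature-curated CNS marker
LHX8	MGE	literature-curated CNS marker
MAF	MGE	literature-curated CNS marker
SST	MGE	literature-curated CNS marker
ERBB4	MGE	literature-curated CNS marker
SOX6	MGE	literature-curated CNS marker
NKX2-1	MGE	literature-curated CNS marker
HES1	NPCs	literature-curated CNS marker
HES5	NPCs	literature-curated CNS marker
TYMS	NPCs	literature-curated CNS marker
FABP7	NPCs	literature-curated CNS marker
EOMES	NPCs	literature-curated CNS marker
NEUROG1	NPCs	literature-curated CNS marker
NCAM1	NPCs	literature-curated CNS marker
TTYH1	NPCs	literature-curated CNS marker
DLX2	NPCs	literature-curated CNS marker
GAD2	NPCs	literature-curated CNS marker
ASCL1	NPCs	literature-curated CNS marker
NEUROG2	NPCs	literature-curated CNS marker
PROX1	NPCs	literature-curated CNS marker
TOP2A	NPCs	literature-curated CNS marker
NUSAP1	NPCs	literature-curated CNS marker
NR2E1	NPCs	literature-curated CNS marker
CD24	NPCs	literature-curated CNS marker
PAX6	NSCs	literature-curated CNS marker
NES	NSCs	literature-curated CNS marker
SOX1	NSCs	literature-curated CNS marker
SOX2	NSCs	literature-curated CNS marker
MCM2	NSCs	literature-curated CNS marker
PCNA	NSCs	literature-curated CNS marker
MKI67	NSCs	literature-curated CNS marker
FOXO3	NSCs	literature-curated CNS marker
BHLHE22	NSCs	literature-curated CNS marker
REST	NSCs	literature-curated CNS marker
HBB	RBC	literature-curated CNS marker
HBM	RBC	literature-curated CNS marker
HBA1	RBC	literature-curated CNS marker
HBA2	RBC	literature-curated CNS marker
IGFBP7	endothelial	literature-curated CNS marker
PECAM1	endothelial	literature-curated CNS marker
KRAT14	epithelial	literature-curated CNS marker
KRAT16	epithelial	literature-curated CNS marker
KRT17	epithelial	literature-curated CNS marker
EMX2	epithelial	literature-curated CNS marker
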
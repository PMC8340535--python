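gene	rna_top5	protein_top5	phospho_top5
PTEN			
STAT3			
NFKB1			
TNF			
AKT1			
IGF1R			
HIF1A			
CAMK2A			
ZEB2			
GSK3B	dysregulated		
ARG1			
FBXW7			
RUNX1			
SIRT1			
ZFPM2			
AKT2			
VEGFA	dysregulated		
EGFR			
YAP1			
ROCK1			
MXI1			
HDAC4			
AKT3	dysregulated		
DNMT1			
MYC			
GSTM1			
CCND1	dysregulated		
CLIC5			
PRKAA1			
FLT1			
GRB2			
ATXN1			
FOXO3			
KIT	dysregulated		
TBX3			
UCP2			
TSC1			
SMAD4			
TIMP3			
BACE1			
RUNX2	dysregulated		
YWHAZ	dysregulated		
IRS1			
KLF4			
EZH2	dysregulated		
HELLS			
BCL2L11			
AKT	dysregulated		
VCAN			
NF1			
SRM			
AMD1			
SEMA4B			
ZEB1			
MEF2C	dysregulated		
CTGF			
KRAS			
CREB1			
RIOK3			
EGR1			
MECP2			
ENPP6	dysregulated		
INPP5D			
ELK1			
PAFAH1B1			
MTOR	dysregulated		
NR1I3			
CAB39			
MEOX2			
SMAD5			
NRAS			
YY1			
RAF1			
CAV2			
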
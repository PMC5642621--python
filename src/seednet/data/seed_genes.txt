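PTGS2
ARID1A
NFKB1
TFF2
STK11
HRAS
MSH2
CTNNB1
MEN1
HIF1A
MTHFR
MAP2K4
AKT1
XRCC1
S100P
KLF5
PARK2
NR5A2
CLPTM1L
GLI1
CDH1
VEGFA
S100A4
CXCR4
BRCA1
SHH
PRSS1
TERT
IGF1R
TP53
IL6
ITGB1
BRCA2
PALB2
MET
CD44
MUC4
MSLN
SSTR2
TNF
KRAS
SMAD4
TGFB1
ERBB2
ROBO2
ATM
BIRC5
MMP9
PTEN
STAT3
EGFR
MMP2
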
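gene	rs
KRT19	1.6
BARD1	1.6
MST1R	1.5
S100A14	1.2
LGALS1	1.2
RNF168	1.1
TFF1	1
SPEN	1
WDR18	0.9
RRAS	0.9
PLEK2	0.8
CD248	0.8
RHBDL2	0.8
CAPN5	0.7
S100A16	0.7
CDC6	0.6
ENDOG	0.6
GNG2	0.6
CLDN18	0.6
RNF169	0.5
NR3C1	0.5
TMC8	0.5
AKT1S1	0.5
KLK10	0.5
SLC2A1	0.5
ANTXR1	0.4
CHSY1	0.4
ELAC1	0.4
PTGES2	0.4
PREX2	0.4
USP1	0.4
EHF	0.4
ADM	0.4
GRM4	0.4
SHFM1	0.4
EMP3	0.4
PTGES	0.3
TRAF1	0.3
NAMPT	0.3
BCL2L12	0.3
MAML1	0.3
USP24	0.3
AMHR2	0.3
PSMG3	0.3
NFE2L2	0.3
RAPH1	0.3
TSHZ2	0.2
RNF146	0.2
NFIL3	0.2
SPINK1	0.2
OSTM1	0.2
ESRRG	0.2
XRCC3	0.2
SLC4A7	0.2
DPH1	0.2
BCL7C	0.2
ZNF18	0.2
PGLS	0.2
CNTN4	0.2
BACH1	0.2
ZFPL1	0.2
MAGED2	0.1
TMEM43	0.1
GALNT5	0.1
HMX1	0.1
RASSF6	0.1
PFN1	0.1
SLC16A7	0.1
ZBTB40	0.1
MAGED4	0.1
PIF1	0.1
MBTPS1	0.1
HDAC4	0.1
VASN	0.1
PSME3	0.1
AMN	0.1
ERCC1	0.1
BRD9	0.1
B4GALNT1	0.1
PLEKHG5	0.1
ARHGAP33	0.1
CYP24A1	0.1
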
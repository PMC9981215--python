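# Synthetic default gene panel: 171 haematologic-neoplasm genes.
# Constructed as a representative stand-in for a commercial 171-gene
# targeted-sequencing panel; gene symbols are real, the exact
# membership is this package's own curation.
ABL1
ABL2
ANKRD26
ARID1A
ARID2
ASXL1
ASXL2
ATM
ATRX
B2M
BCL10
BCL2
BCL2L11
BCL6
BCL7A
BCOR
BCORL1
BIRC3
BRAF
BRCC3
BRINP3
BTG1
BTG2
BTK
CALR
CARD11
CBL
CBLB
CCND1
CCND3
CD79A
CD79B
CDK4
CDK6
CDKN2A
CDKN2B
CEBPA
CHD2
CIITA
CREBBP
CSF1R
CSF2RB
CSF3R
CSNK1A1
CTCF
CTNNB1
CUX1
CXCR4
DDX3X
DDX41
DIS3
DNMT1
DNMT3A
DUSP2
EBF1
EED
EGR2
ELANE
EP300
EPOR
ETNK1
ETS1
ETV6
EZH2
FAM46C
FAS
FBXW7
FGFR3
FLT3
FOXO1
GATA1
GATA2
GATA3
GNA13
GNAS
GNB1
HRAS
ID3
IDH1
IDH2
IKZF1
IKZF3
IL7R
IRF4
IRF8
JAK1
JAK2
JAK3
KDM6A
KIT
KLF2
KLHL6
KMT2A
KMT2D
KRAS
LUC7L2
MAP2K1
MAPK1
MED12
MEF2B
MGA
MLLT3
MPL
MYB
MYC
MYCN
MYD88
NF1
NFKB1
NFKBIE
NOTCH1
NOTCH2
NPM1
NRAS
NT5C2
PAX5
PDGFRA
PDGFRB
PDS5B
PHF6
PIGA
PIK3CA
PLCG2
POT1
PPM1D
PRDM1
PRKCB
PRPF8
PTEN
PTPN11
PTPRC
RAD21
RB1
RELN
RHOA
RPS15
RUNX1
SAMHD1
SETBP1
SETD1A
SETD2
SF1
SF3A1
SF3B1
SGK1
SH2B3
SMARCA4
SMC1A
SMC3
SOCS1
SPEN
SRSF2
STAG1
STAG2
STAT3
STAT5B
SUZ12
TBL1XR1
TCF3
TERT
TET2
TNFAIP3
TP53
TRAF3
U2AF1
U2AF2
UBA1
WT1
XPO1
ZMYM3
ZRSR2
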
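# Reportable fusion gene footprint (284 genes)
ABCB1
ABL1
AKAP9
AKT1
AKT2
AKT3
ALK
APC
AR
ARAF
AREG
ARID1A
ASXL1
ATM
ATR
ATRX
AURKA
AXL
BAP1
BCL2
BCL6
BCOR
BCORL1
BCR
BRAF
BRCA1
BRCA2
BRD4
BRIP1
BTK
CALR
CAMTA1
CBFB
CBL
CCNB3
CCND1
CCND2
CCND3
CCNE1
CD274
CD276
CD40
CDH1
CDH3
CDK4
CDK6
CDK9
CDKN1A
CDKN1B
CDKN2A
CDKN2B
CEBPA
CHEK1
CHEK2
CIC
CREBBP
CRKL
CRLF2
CRTC1
CSF1R
CSF3R
CTAG2
CTLA4
CTNNB1
CUX1
DDR2
DEK
DKK1
DLL3
DNMT3A
EGFR
EML4
EP300
EPCAM
ERBB2
ERBB3
ERBB4
ESR1
ESR2
ETV6
EWSR1
EZH2
EZHIP
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
FBXW7
FCER2
FGF19
FGF2
FGFR1
FGFR2
FGFR3
FGFR4
FH
FLCN
FLT1
FLT3
FLT4
FOLR1
FOXL2
FOXO1
FUS
FYN
GATA1
GATA2
GLI2
GNA11
GNAQ
GNAS
GPNMB
HEY1
HNF1A
HRAS
HSP90AA1
IDH1
IDH2
IGF1R
IKZF1
IL2RA
JAK1
JAK2
JAK3
KDM6A
KDR
KIT
KLB
KMT2A
KRAS
LAG3
MAGEA3
MAGEA4
MAP2K1
MAP2K2
MAP2K4
MAP3K1
MAPK1
MBTD1
MCL1
MDM2
MDM4
MECOM
MEN1
MET
MKL1
MLH1
MLLT3
MPL
MRE11A
MS4A1
MSH2
MSH6
MSLN
MTOR
MUTYH
MYC
MYCN
MYD88
MYH11
MYOD1
NAB2
NF1
NF2
NFE2L2
NKX2-1
NOTCH1
NOTCH2
NOTCH3
NPM1
NR4A3
NRAS
NRG1
NTRK1
NTRK2
NTRK3
NUP214
NUTM2A
PALB2
PARP1
PAX3
PDCD1
PDCD1LG2
PDGFB
PDGFRA
PDGFRB
PGR
PHF1
PIK3CA
PIK3CB
PIK3CD
PIK3CG
PIK3R1
PML
PMS2
POLE
PRAME
PRKACA
PRKCA
PRKCB
PRKCD
PRKCE
PRKCG
PRKCI
PRKCQ
PRKCZ
PSCA
PTCH1
PTEN
PTK2
PTPN11
PVRL4
RAD21
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAF1
RARA
RB1
RBM15
RELA
RET
RICTOR
ROS1
RPN1
RUNX1
RUNX1T1
SDHB
SDHC
SDHD
SETBP1
SF3B1
SHH
SLX4
SMAD4
SMARCA4
SMARCB1
SMC1A
SMC3
SMO
SRC
SRSF2
SS18
STAG2
STAT3
STAT5B
STAT6
STK11
SULT1A1
SUZ12
SYK
TERT
TET2
TFE3
TGFBR1
TGFBR2
TMPRSS2
TNFRSF4
TNFRSF8
TP53
TSC1
TSC2
U2AF1
VEGFA
VEGFB
VGLL2
VHL
WEE1
WT1
WWTR1
XPO1
XRCC1
YAP1
YES1
YWHAE
ZRSR2
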
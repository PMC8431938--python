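# Default cancer-predisposition gene list (152 genes) used by the
# non-cancer triage step. One symbol per line; '#' starts a comment.
# Editable: pass --cancer-genes FILE to override.
ABRAXAS1
ACD
AIP
ALK
ANKRD26
APC
ATM
ATR
AXIN2
BAP1
BARD1
BLM
BMPR1A
BRCA1
BRCA2
BRIP1
BUB1B
CBL
CDC73
CDH1
CDK4
CDKN1B
CDKN1C
CDKN2A
CEBPA
CEP57
CHEK2
CTNNA1
CYLD
DDB2
DDX41
DGCR8
DICER1
DIS3L2
DKC1
DROSHA
EGFR
EPCAM
ERCC2
ERCC3
ERCC4
ERCC5
ETV6
EXT1
EXT2
EZH2
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
FH
FLCN
GATA2
GPC3
GREM1
HNF1A
HOXB13
HRAS
KIF1B
KIT
LZTR1
MAX
MEN1
MET
MITF
MLH1
MLH3
MRE11A
MSH2
MSH3
MSH6
MUTYH
NBN
NF1
NF2
NHP2
NOP10
NRAS
NSD1
NTHL1
PALB2
PAX5
PHOX2B
PMS1
PMS2
POLD1
POLE
POLH
POT1
PRF1
PRKAR1A
PTCH1
PTEN
PTPN11
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RB1
RECQL4
RET
RHBDF2
RNF43
RUNX1
SAMD9
SAMD9L
SBDS
SDHA
SDHAF2
SDHB
SDHC
SDHD
SETBP1
SH2D1A
SLX4
SMAD4
SMARCA4
SMARCB1
SMARCE1
SOS1
SPRED1
SRP72
SRY
STAT3
STK11
SUFU
TERC
TERF2IP
TERT
TMEM127
TP53
TP63
TRIM37
TSC1
TSC2
TSHR
VHL
WAS
WRAP53
WRN
WT1
XPA
XPC
XRCC2
XRCC3
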
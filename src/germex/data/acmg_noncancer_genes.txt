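# The 34 genes of the ACMG SF v2.0 secondary-findings list (59 genes)
# that are not cancer-related; used by the permissive recall filter.
ACTA2
ACTC1
APOB
ATP7B
CACNA1S
COL3A1
DSC2
DSG2
DSP
FBN1
GLA
KCNH2
KCNQ1
LDLR
LMNA
MYBPC3
MYH11
MYH7
MYL2
MYL3
OTC
PCSK9
PKP2
PRKAG2
RYR1
RYR2
SCN5A
SMAD3
TGFBR1
TGFBR2
TMEM43
TNNI3
TNNT2
TPM1
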
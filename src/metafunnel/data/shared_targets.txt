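ADORA3
AKR1B1
AR
CHRNA7
CYP19A1
FABP3
FDFT1
FNTA
FNTB
FOLH1
GBA1
HMGCR
HSD11B1
NPC1L1
NR1H4
POLB
PPARA
PPARD
PTGER2
PTPN1
SHBG
SLC22A6
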
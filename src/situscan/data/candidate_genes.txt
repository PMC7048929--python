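# Default candidate laterality / ciliopathy gene list.
# Reconstructed from genes discussed in the situs inversus literature this
# pipeline targets (human laterality disorders, PCD, cellular chirality and
# handedness-associated loci); supply your own curated list to replace it.
ZIC3
CCDC11
CFAP52
WDR16
NME7
PKD1L1
MMP21
ROCK2
RAI2
KIF3A
KIF3B
KIF13B
MYO1D
MYO1C
SLC6A4
SLC18A2
MAP2
LRRC6
DNAH5
DNAH11
DNAAF1
CCDC114
CCDC151
PKD1
WDR62
PLXND1
SPEF2
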
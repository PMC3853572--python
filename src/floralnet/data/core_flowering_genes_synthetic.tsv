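# Synthetic stand-in for a curated list of 109 Arabidopsis flowering/floral
# core regulators. Gene symbols are real, well-known flowering-pathway genes;
# the list composition is this package's own curation, not the original
# study's unarchived table. Columns: gene symbol, optional locus note.
FT
TSF
FLC
LFY
AP1
AP2
AP3
PI
AG
SEP1
SEP2
SEP3
SEP4
SOC1
CO
COL1
COL2
GI
CCA1
LHY
TOC1
PRR5
PRR7
PRR9
ELF3
ELF4
ELF5
ELF6
ELF7
ELF8
ELF9
CRY1
CRY2
PHYA
PHYB
PHYC
PHYD
PHYE
COP1
SPA1
CIB1
CIB5
FKF1
ZTL
LKP2
CDF1
SVP
AGL24
AGL19
AGL12
FUL
CAL
TFL1
TFL2
FD
FDP
FRI
FRL1
FRL2
FCA
FY
FPA
FLD
FVE
FLK
LD
REF6
VIN3
VIL1
VRN1
VRN2
VRN5
CLF
SWN
MEA
EMF1
EMF2
PIE1
ARP4
ARP6
SUF4
HUA2
NUA
SRT1
SRT2
H2B
UBC1
UBC2
VIP3
VIP4
VIP5
VIP6
MAF1
MAF2
MAF3
MAF4
MAF5
MBD9
SPY
GA1
GAI
RGA
RGL1
RGL2
GID1A
XAL1
CCR2
SMZ
SNZ
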
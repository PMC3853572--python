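# Synthetic stand-in edge list for a literature-curated Arabidopsis
# flowering regulatory network. Edges are canonical, well-documented
# regulatory relations among flowering-pathway genes; the compilation is
# this package's own reduced curation, shipped as a static fixture only.
# Columns: regulator, target, pathway.
PHYA	CO	photoperiod
PHYB	CO	photoperiod
CRY1	CO	photoperiod
CRY2	CO	photoperiod
GI	CO	photoperiod
GI	FT	photoperiod
CCA1	TOC1	photoperiod
LHY	TOC1	photoperiod
TOC1	CCA1	photoperiod
ELF3	GI	photoperiod
ELF4	CCA1	photoperiod
FKF1	CDF1	photoperiod
CDF1	CO	photoperiod
ZTL	TOC1	photoperiod
COP1	CO	photoperiod
SPA1	CO	photoperiod
CO	FT	integration
CO	SOC1	integration
FT	SOC1	integration
FT	AP1	integration
FD	AP1	integration
SOC1	LFY	integration
AGL24	SOC1	integration
SVP	FT	integration
SVP	SOC1	integration
FLC	FT	vernalization
FLC	SOC1	vernalization
FRI	FLC	vernalization
VIN3	FLC	vernalization
VRN1	FLC	vernalization
VRN2	FLC	vernalization
CLF	FLC	vernalization
PIE1	FLC	vernalization
ARP6	FLC	vernalization
ELF7	FLC	vernalization
ELF8	FLC	vernalization
UBC1	FLC	vernalization
UBC2	FLC	vernalization
FCA	FLC	autonomous
FY	FLC	autonomous
FPA	FLC	autonomous
FLD	FLC	autonomous
FVE	FLC	autonomous
FLK	FLC	autonomous
LD	FLC	autonomous
SPY	GA1	gibberellin
GA1	LFY	gibberellin
GAI	LFY	gibberellin
RGA	LFY	gibberellin
LFY	AP1	floral
LFY	AP3	floral
LFY	AG	floral
AP1	AP2	floral
AP1	SEP3	floral
AP2	AG	floral
SEP3	AP3	floral
SEP3	PI	floral
AG	SEP3	floral
TFL1	LFY	floral
TFL1	AP1	floral
XAL1	SOC1	integration
MAF1	FT	vernalization
SMZ	FT	integration
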
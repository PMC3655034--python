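# Coarse backbone-independent rotamer table packaged with the artifact so
# the side-chain search runs with no external download.  Means/sigmas
# (degrees) and probabilities are round-number summaries of the canonical
# gauche-/trans/gauche+ preferences seen in curated rotamer surveys; a
# proper backbone-dependent library (Dunbrack text format) can be supplied
# instead and takes precedence when given.
# Syntax: RES bin prob chi1_mean chi1_sigma [chi2_mean chi2_sigma ...]
# ('-' marks a backbone-independent entry.)
backbone_dependent 0

SER - 0.48 -65.0 10.0
SER - 0.30 180.0 10.0
SER - 0.22 62.0 10.0

CYS - 0.50 -65.0 10.0
CYS - 0.30 180.0 10.0
CYS - 0.20 62.0 10.0

THR - 0.49 62.0 10.0
THR - 0.43 -61.0 10.0
THR - 0.08 -175.0 10.0

VAL - 0.73 175.0 10.0
VAL - 0.20 -60.0 10.0
VAL - 0.07 65.0 10.0

LEU - 0.60 -65.0 10.0 175.0 12.0
LEU - 0.30 177.0 10.0 63.0 12.0
LEU - 0.10 -172.0 10.0 145.0 14.0

ILE - 0.60 -65.0 10.0 170.0 12.0
ILE - 0.25 62.0 10.0 170.0 12.0
ILE - 0.15 -57.0 10.0 -60.0 12.0

MET - 0.30 -65.0 10.0 180.0 12.0 75.0 14.0
MET - 0.30 -65.0 10.0 180.0 12.0 -75.0 14.0
MET - 0.20 -65.0 10.0 -65.0 12.0 -70.0 14.0
MET - 0.20 180.0 10.0 180.0 12.0 75.0 14.0

ASP - 0.55 -70.0 10.0 -15.0 18.0
ASP - 0.25 -170.0 10.0 5.0 18.0
ASP - 0.20 62.0 10.0 -10.0 18.0

ASN - 0.45 -65.0 10.0 -40.0 16.0
ASN - 0.30 -170.0 10.0 60.0 16.0
ASN - 0.25 62.0 10.0 -75.0 16.0

GLU - 0.40 -65.0 10.0 180.0 12.0 -10.0 18.0
GLU - 0.30 -70.0 10.0 -80.0 12.0 0.0 18.0
GLU - 0.30 180.0 10.0 180.0 12.0 0.0 18.0

GLN - 0.40 -65.0 10.0 180.0 12.0 -25.0 18.0
GLN - 0.30 -70.0 10.0 -75.0 12.0 0.0 18.0
GLN - 0.30 180.0 10.0 180.0 12.0 20.0 18.0

LYS - 0.40 -65.0 10.0 180.0 12.0 180.0 12.0 180.0 12.0
LYS - 0.35 180.0 10.0 180.0 12.0 180.0 12.0 180.0 12.0
LYS - 0.25 -65.0 10.0 -65.0 12.0 180.0 12.0 180.0 12.0

ARG - 0.35 -65.0 10.0 180.0 12.0 180.0 12.0 180.0 14.0
ARG - 0.35 -65.0 10.0 -65.0 12.0 180.0 12.0 85.0 14.0
ARG - 0.30 180.0 10.0 180.0 12.0 180.0 12.0 180.0 14.0

HIS - 0.35 -65.0 10.0 -70.0 14.0
HIS - 0.35 -170.0 10.0 65.0 14.0
HIS - 0.30 62.0 10.0 -85.0 14.0

PHE - 0.50 -65.0 10.0 95.0 15.0
PHE - 0.35 180.0 10.0 75.0 15.0
PHE - 0.15 62.0 10.0 90.0 15.0

TYR - 0.50 -65.0 10.0 95.0 15.0
TYR - 0.35 180.0 10.0 75.0 15.0
TYR - 0.15 62.0 10.0 90.0 15.0

TRP - 0.35 -65.0 10.0 95.0 15.0
TRP - 0.35 180.0 10.0 -105.0 15.0
TRP - 0.30 62.0 10.0 -90.0 15.0

PRO - 0.50 -27.0 8.0 39.0 8.0
PRO - 0.50 28.0 8.0 -40.0 8.0
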
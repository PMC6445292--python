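# Residue-type normalization factors for protein structure network
# interaction strengths (side-chain contact counts), as distributed with
# the Wordom implementation of the method.
# residue_name	normalization
ALA	55.7551
ARG	93.7891
ASN	73.4097
ASP	75.1507
CYS	54.9528
GLN	78.1301
GLU	78.8288
GLY	47.3129
HIS	83.7357
ILE	67.9452
LEU	72.2517
LYS	69.6096
MET	69.2569
PHE	93.3082
PRO	51.3310
SER	61.3946
THR	63.7075
TRP	106.7030
TYR	100.7190
VAL	62.3673
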
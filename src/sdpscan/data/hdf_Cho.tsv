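# Hydrophobicity as proportion of 95% buried residues (Chothia)
# Transcribed from: Chothia C. (1976) J. Mol. Biol. 105:1-12, as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	0.38
R	0.01
N	0.12
D	0.15
C	0.50
Q	0.07
E	0.18
G	0.36
H	0.17
I	0.60
L	0.45
K	0.03
M	0.40
F	0.50
P	0.18
S	0.22
T	0.23
W	0.27
Y	0.15
V	0.54
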
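# Relative mutability of the 20 amino acids (Ala = 100)
# Transcribed from: Dayhoff M.O., Schwartz R.M., Orcutt B.C. (1978), as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	100
R	65
N	134
D	106
C	20
Q	93
E	102
G	49
H	66
I	96
L	40
K	56
M	94
F	41
P	56
S	120
T	97
W	18
Y	41
V	74
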
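# Molecular weight of each amino acid (Daltons)
# Transcribed from: Most amino-acid biochemistry references; values as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	89.000
R	174.000
N	132.000
D	133.000
C	121.000
Q	146.000
E	147.000
G	75.000
H	155.000
I	131.000
L	131.000
K	146.000
M	149.000
F	165.000
P	115.000
S	105.000
T	119.000
W	204.000
Y	181.000
V	117.000
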
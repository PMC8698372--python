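# Conformational parameter for coil (Deleage & Roux)
# Transcribed from: Deleage G., Roux B. (1987) Protein Eng. 1:289-294, as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	0.824
R	0.893
N	1.167
D	1.197
C	0.953
Q	0.947
E	0.761
G	1.251
H	1.068
I	0.886
L	0.517
K	0.897
M	0.551
F	0.797
P	1.540
S	1.130
T	1.148
W	0.941
Y	1.109
V	0.772
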
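# Conformational parameter for alpha-helix (Deleage & Roux)
# Transcribed from: Deleage G., Roux B. (1987) Protein Eng. 1:289-294, as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	1.489
R	1.224
N	0.772
D	0.924
C	0.966
Q	1.164
E	1.504
G	0.510
H	1.003
I	1.003
L	1.236
K	1.172
M	1.363
F	1.195
P	0.492
S	0.739
T	0.785
W	1.090
Y	0.787
V	0.990
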
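# Atchley factor I: polarity / accessibility / hydrophobicity
# Transcribed from: Atchley W.R., Zhao J., Fernandes A.D., Druke T. (2005) Proc. Natl. Acad. Sci. USA 102:6395-6400, Table 2
# Values stored at the precision published by the source.
A	-0.591
R	1.538
N	0.945
D	1.050
C	-1.343
Q	0.931
E	1.357
G	-0.384
H	0.336
I	-1.239
L	-1.019
K	1.831
M	-0.663
F	-1.006
P	0.189
S	-0.228
T	-0.032
W	-0.595
Y	0.260
V	-1.337
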
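# Atchley factor IV: codon composition / relative amino-acid composition
# Transcribed from: Atchley W.R., Zhao J., Fernandes A.D., Druke T. (2005) Proc. Natl. Acad. Sci. USA 102:6395-6400, Table 2
# Values stored at the precision published by the source.
A	1.570
R	0.440
N	-0.169
D	-0.259
C	-1.020
Q	-0.503
E	0.113
G	1.045
H	-1.474
I	0.393
L	1.266
K	-0.277
M	-1.005
F	-0.397
P	0.421
S	0.670
T	0.908
W	-2.128
Y	-0.838
V	1.242
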
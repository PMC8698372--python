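# Atchley factor III: molecular size / volume
# Transcribed from: Atchley W.R., Zhao J., Fernandes A.D., Druke T. (2005) Proc. Natl. Acad. Sci. USA 102:6395-6400, Table 2
# Values stored at the precision published by the source.
A	-0.733
R	1.502
N	1.299
D	-3.656
C	-0.862
Q	-3.005
E	1.477
G	1.330
H	-1.673
I	2.131
L	-1.505
K	0.533
M	2.219
F	1.891
P	-1.628
S	-4.760
T	2.213
W	0.672
Y	3.097
V	-0.544
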
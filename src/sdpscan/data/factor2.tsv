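# Atchley factor II: propensity for secondary structure
# Transcribed from: Atchley W.R., Zhao J., Fernandes A.D., Druke T. (2005) Proc. Natl. Acad. Sci. USA 102:6395-6400, Table 2
# Values stored at the precision published by the source.
A	-1.302
R	-0.055
N	0.828
D	0.302
C	0.465
Q	-0.179
E	-1.453
G	1.652
H	-0.417
I	-0.547
L	-0.987
K	-0.561
M	-1.524
F	-0.590
P	2.081
S	1.399
T	0.326
W	0.009
Y	0.830
V	-0.279
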
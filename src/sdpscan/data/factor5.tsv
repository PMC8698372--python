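# Atchley factor V: electrostatic charge
# Transcribed from: Atchley W.R., Zhao J., Fernandes A.D., Druke T. (2005) Proc. Natl. Acad. Sci. USA 102:6395-6400, Table 2
# Values stored at the precision published by the source.
A	-0.146
R	2.897
N	0.933
D	-3.242
C	-0.255
Q	-1.853
E	-0.837
G	2.064
H	-0.078
I	0.816
L	-0.912
K	1.648
M	1.212
F	0.412
P	-1.392
S	-2.647
T	1.313
W	-0.184
Y	1.512
V	-1.262
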
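# Average flexibility index
# Transcribed from: Bhaskaran R., Ponnuswamy P.K. (1988) Int. J. Pept. Protein Res. 32:241-255, as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	0.357
R	0.529
N	0.463
D	0.511
C	0.346
Q	0.493
E	0.497
G	0.544
H	0.323
I	0.462
L	0.365
K	0.466
M	0.295
F	0.314
P	0.509
S	0.507
T	0.444
W	0.305
Y	0.420
V	0.386
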
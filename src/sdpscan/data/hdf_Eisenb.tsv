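# Normalized consensus hydrophobicity (Eisenberg)
# Transcribed from: Eisenberg D., Schwarz E., Komaromy M., Wall R. (1984) J. Mol. Biol. 179:125-142, as distributed by the ExPASy ProtScale server
# Values stored at the precision published by the source.
A	0.620
R	-2.530
N	-0.780
D	-0.900
C	0.290
Q	-0.850
E	-0.740
G	0.480
H	-0.400
I	1.380
L	1.060
K	-1.500
M	0.640
F	1.190
P	0.120
S	-0.180
T	-0.050
W	0.810
Y	0.260
V	1.080
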
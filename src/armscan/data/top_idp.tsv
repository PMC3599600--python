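# TOP-IDP disorder propensity scale (Campen et al. 2008, Protein Pept Lett 15:956-963).
# Higher values = stronger disorder promotion. Used by armscan.composition.disorder_proxy.
residue	propensity
A	0.060
R	0.180
N	0.007
D	0.192
C	0.020
Q	0.318
E	0.736
G	0.166
H	0.303
I	-0.486
L	-0.326
K	0.586
M	-0.397
F	-0.697
P	0.987
S	0.341
T	0.059
W	-0.884
Y	-0.510
V	-0.121
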
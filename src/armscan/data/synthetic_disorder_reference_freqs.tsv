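# SYNTHETIC stand-in reference table: per-residue background frequencies of a
# disordered-domain set vs an ordered-domain set. These are NOT measured database
# frequencies; they are plausible values for closed-box runs and tests. Replace with
# your own table (same columns) for real analyses: disorder_enrichment accepts any
# DataFrame/TSV with columns residue, disordered, ordered.
residue	disordered	ordered
A	0.076	0.079
R	0.059	0.048
N	0.033	0.045
D	0.056	0.058
C	0.009	0.017
Q	0.052	0.037
E	0.094	0.062
G	0.080	0.073
H	0.020	0.022
I	0.031	0.057
L	0.063	0.090
K	0.077	0.058
M	0.017	0.022
F	0.023	0.041
P	0.081	0.044
S	0.093	0.059
T	0.054	0.055
W	0.006	0.014
Y	0.018	0.034
V	0.058	0.085
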
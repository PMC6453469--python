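# synthetic stand-in generated by cldmd.synthetic around the real
# alpha-synuclein sequence on a seeded claw-like trace (seed 20260101);
# emulates the shape of the experimental supplement, not its values
residue,hl_ratio
1,1.858
6,0.830
10,0.847
12,2.326
21,0.797
23,0.997
32,2.241
34,1.816
43,1.210
45,0.786
58,1.171
60,0.913
80,1.776
96,1.122
97,0.856
102,1.146
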
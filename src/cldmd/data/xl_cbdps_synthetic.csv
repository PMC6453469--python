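# synthetic stand-in generated by cldmd.synthetic around the real
# alpha-synuclein sequence on a seeded claw-like trace (seed 20260101);
# emulates the shape of the experimental supplement, not its values
res_i,res_j,reagent
1,6,CBDPS
12,23,CBDPS
21,32,CBDPS
21,43,CBDPS
34,43,CBDPS
97,102,CBDPS
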
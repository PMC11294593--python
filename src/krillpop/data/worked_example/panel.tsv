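sample_id	population_id
p1_1	pop1
p1_2	pop1
p2_1	pop2
p2_2	pop2
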
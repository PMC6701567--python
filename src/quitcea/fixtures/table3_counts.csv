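sex,age_group,n_hit_short,n_lit_short,n_hit_long,n_lit_long
female,20-24,0,1,0,0
female,25-29,1,0,0,0
female,35-39,2,2,1,1
female,40-44,5,0,4,0
female,45-49,3,3,1,2
female,50-54,4,3,1,2
female,55-59,4,2,4,1
female,60-64,4,0,2,0
female,65-69,0,1,0,0
male,20-24,1,0,1,0
male,40-44,1,0,1,0
male,45-49,1,1,1,1
male,50-54,0,1,0,0
male,65-69,1,0,1,0
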
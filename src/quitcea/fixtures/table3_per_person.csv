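sex,age_group,costs_avoided,qalys_gained
female,20-24,8142,0.61
female,25-29,8425,0.65
female,35-39,9267,0.71
female,40-44,8532,0.71
female,45-49,6772,0.66
female,50-54,5228,0.61
female,55-59,4542,0.43
female,60-64,3336,0.32
female,65-69,2023,0.33
male,20-24,10430,0.74
male,40-44,10526,1.00
male,45-49,11416,0.82
male,50-54,11360,0.78
male,65-69,4084,0.46
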
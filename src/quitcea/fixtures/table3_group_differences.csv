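sex,age_group,horizon,costs,qalys
female,20-24,short,-8142,-0.61
female,25-29,short,8425,0.65
female,35-39,short,0,0
female,40-44,short,42658,3.55
female,45-49,short,0,0
female,50-54,short,5228,0.61
female,55-59,short,9085,0.86
female,60-64,short,13342,1.29
female,65-69,short,-2023,-0.33
male,20-24,short,10430,0.74
male,40-44,short,10526,1.00
male,45-49,short,0,0
male,50-54,short,-11360,-0.78
male,65-69,short,4084,0.46
female,35-39,long,0,0
female,40-44,long,34126,2.84
female,45-49,long,-6772,-0.66
female,50-54,long,-5228,-0.61
female,55-59,long,13627,1.29
female,60-64,long,6671,0.64
male,20-24,long,10430,0.74
male,40-44,long,10526,1.00
male,45-49,long,0,0
male,65-69,long,4084,0.46
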
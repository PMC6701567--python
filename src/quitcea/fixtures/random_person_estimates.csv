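sex,costs_avoided,qalys_gained
male,9740,0.83
female,7165,0.66
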
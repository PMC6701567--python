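term,coefficient,p_value,odds_ratio,ci_low,ci_high
programme,1.001,0.03,2.72,1.09,6.80
gender,-0.077,0.88,0.93,0.32,2.64
age,0.005,0.82,1.00,0.96,1.05
intercept,-3.124,0.01,0.04,,
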
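measure,hit,lit
randomised,150,150
baseline_measures,146,148
followup_12m,132,122
available_long_term,141,143
followup_long_term,121,120
men,26,32
women,115,111
continuous_abstinence_1y,27,14
sustained_abstinence,17,7
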
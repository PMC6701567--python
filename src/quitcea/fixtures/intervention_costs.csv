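programme,total_specific_cost,n_participants,per_participant_cost
HIT,117011,146,801
LIT,27927,148,189
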
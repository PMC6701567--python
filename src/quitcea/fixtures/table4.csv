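scenario,field,value
short,intervention_cost_hit,117011
short,intervention_cost_lit,27927
short,intervention_cost_diff,89085
short,societal_costs_avoided,82253
short,incremental_cost,6832
short,incremental_qalys,7.44
short,icer,918
long,intervention_cost_hit,117011
long,intervention_cost_lit,27927
long,intervention_cost_diff,89085
long,societal_costs_avoided,67466
long,incremental_cost,21619
long,incremental_qalys,5.71
long,icer,3786
long_sensitivity,intervention_cost_hit,117011
long_sensitivity,intervention_cost_lit,27927
long_sensitivity,intervention_cost_diff,89085
long_sensitivity,societal_costs_avoided,32469
long_sensitivity,incremental_cost,56616
long_sensitivity,incremental_qalys,4.82
long_sensitivity,icer,11746
per_person_men,intervention_cost_hit,801
per_person_men,intervention_cost_lit,189
per_person_men,intervention_cost_diff,612
per_person_men,societal_costs_avoided,779
per_person_men,incremental_cost,-167
per_person_men,incremental_qalys,0.0664
per_person_men,icer,
per_person_women,intervention_cost_hit,801
per_person_women,intervention_cost_lit,189
per_person_women,intervention_cost_diff,612
per_person_women,societal_costs_avoided,502
per_person_women,incremental_cost,110
per_person_women,incremental_qalys,0.0462
per_person_women,icer,2391
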
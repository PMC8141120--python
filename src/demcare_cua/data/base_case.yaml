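# Packaged base case: two-arm parameter set and model configuration for the
# deprescribing cost-utility analysis. Values match base_case_arms() /
# base_case_config(); edit a copy to run scenario variants.
control:
  incidence: 0.40
  recovery: 0.0
  rr_baseline: 1.0
  rr_deteriorated: 1.51
  cost_baseline: 0.0
  cost_deteriorated: 2265.68
  intervention_recurrent_cost: 0.0
  intervention_oneoff_cost: 0.0
  utility_baseline: 0.70
  utility_deteriorated: 0.27
intervention:
  incidence: 0.40
  recovery: 0.0
  rr_baseline: 1.0
  rr_deteriorated: 1.31
  cost_baseline: 0.0
  cost_deteriorated: 1630.335
  intervention_recurrent_cost: 48.56
  intervention_oneoff_cost: 0.0
  utility_baseline: 0.70
  utility_deteriorated: 0.27
model:
  age_min: 65
  age_max: 90
  horizon_cycles: 1
  cycle_length_years: 1
  discount_rate_costs: 0.0
  discount_rate_effects: 0.0
  initial_state_distribution: [0.0, 1.0]
  sex_mix: 0.75
  population_size: 200
  population_start_age: 87
  wtp_threshold: 15000.0
  half_cycle_correction: false
  recurrent_cost_scope: alive
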
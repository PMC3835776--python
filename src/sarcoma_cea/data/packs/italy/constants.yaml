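country: italy
utilities:
  cr: 0.6
  pr: 0.51
  sd: 0.43
  pd: 0.3
cycle_length_months: 1
horizon_cycles: 24
discount_rate: 0.03
first_line_switch_cycle: 3
second_line_eval_cycles: 3
mean_course_cycles: 6
psa_iterations: 10000
dsa_fraction: 0.2
ceac_reference_threshold: 35000
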
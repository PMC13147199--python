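p_recurrent:
  dist: beta
  mean: 0.149
  sd: 0.008
p_mort_background:
  dist: beta
  mean: 0.02
  sd: 0.004
p_mort_poststroke:
  dist: beta
  mean: 0.05
  sd: 0.01
u_stable:
  dist: beta
  mean: 0.9
  sd: 0.15
u_recurrent:
  dist: beta
  mean: 0.5
  sd: 0.15
rrr:
  dist: ldl_mapped_rrr
  rrr_base: 0.32
  red_mean: 0.6
  red_sd: 0.05
price_multiplier:
  dist: gamma
  mean: 1.0
  cv: 0.2
c_stroke_state_annual:
  dist: gamma
  mean: 14800.0
  cv: 0.085
c_stroke_event_acute:
  dist: gamma
  mean: 25900.0
  cv: 0.085
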
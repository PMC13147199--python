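p_recurrent_annual: 0.149
p_mort_background_annual: 0.02
p_mort_poststroke_annual: 0.05
u_stable: 0.9
u_recurrent: 0.5
discount_rate_annual: 0.03
discontinuation_annual: 0.07
rrr: 0.32
price:
  name: alirocumab
  annual_cost_by_year:
  - 6600.0
  - 6600.0
  - 6600.0
  - 6600.0
  - 6600.0
c_stroke_state_annual: 14800.0
c_stroke_event_acute: 25900.0
horizon_years: 5
rrr_scale: rate
cycle_accounting: end
drug_cost_basis: annuity
discontinuation_removes_effect: false
u_dead: 0.0
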
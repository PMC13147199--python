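# Scenario grid consumed by `icas-cea scenarios --grid ...`.
# price_schedule is a builtin name or an inline mapping.
- name: alirocumab_base
  price_schedule: alirocumab
- name: alirocumab_conservative
  price_schedule: alirocumab
  rrr_override: 0.20
- name: alirocumab_optimistic
  price_schedule: alirocumab
  rrr_override: 0.50
- name: alirocumab_low_care_costs
  price_schedule: alirocumab
  stroke_cost_multiplier: 0.5
- name: alirocumab_high_care_costs
  price_schedule: alirocumab
  stroke_cost_multiplier: 1.5
- name: alirocumab_out_of_pocket
  price_schedule: alirocumab_oop
- name: flat_3000
  price_schedule: {name: flat_3000, annual_cost_by_year: [3000, 3000, 3000, 3000, 3000]}
- name: flat_8000
  price_schedule: {name: flat_8000, annual_cost_by_year: [8000, 8000, 8000, 8000, 8000]}
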
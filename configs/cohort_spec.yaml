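n: 367
seed: 0
age_location: 60.0
age_scale: 12.5
ldl_baseline_location: 4.51085950651685
ldl_baseline_scale: 0.354
ldl_change_location: 0.21
ldl_change_scale: 0.18
ldl_change_bounds:
- -0.3
- 0.95
covariate_prevalences:
  hypertension: 0.899
  diabetes: 0.406
  smoking: 0.376
male_fraction: 0.638
log_hr_per_unit_log_ldl: 0.57
baseline_annual_hazard: 0.215
weibull_shape: 1.0
followup_days_range:
- 131.0
- 506.0
censoring_rate: 0.02
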
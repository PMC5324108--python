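# Default synthetic-cohort calibration.
#
# Factor prevalences are the control-arm prevalences of the six modifiable
# risk indicators; effect sizes are the fitted multivariate odds ratios of
# the score-level risk model (per environmental factor, family history,
# per risk allele).
n_cases: 1336
n_controls: 2744
factor_prevalences:
  alcohol_high: 0.1556
  obese: 0.0685
  no_physical_activity: 0.3852
  low_vegetables: 0.6917
  high_red_meat: 0.4093
  no_nsaid_asa: 0.2730
fh_prevalence: 0.1214
smoking_prevalence: 0.5645
true_or_per_factor: 1.36
true_or_fh: 2.25
true_or_per_allele: 1.07
baseline_logit: -3.0
age_distribution:
  "25": 0.010
  "30": 0.015
  "35": 0.025
  "40": 0.040
  "45": 0.060
  "50": 0.100
  "55": 0.125
  "60": 0.140
  "65": 0.150
  "70": 0.140
  "75": 0.110
  "80": 0.085
sex_ratio: 0.55
n_regions: 12
missing_rates: {}
seed: 20170224
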
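# Default model configuration: lifetime Markov cohort model of inclisiran +
# statin versus statin alone in Chinese dyslipidemia patients.
#
# Each uncertain parameter carries {baseline, low, high, family}.  `family`
# selects the PSA sampling distribution: beta (probabilities/utilities),
# gamma (costs), lognormal (risk ratios, matched to the 95% CI), or fixed
# (never sampled).  Missing low/high default to +/-20% of baseline for
# non-fixed parameters.

settings:
  start_age: 60          # cohort entry age, years (statin cohort mean ~59.8)
  max_age: 100           # forced absorption age
  cycle_length: 1        # years per Markov cycle
  discount_rate: {baseline: 0.05, low: 0.0, high: 0.08, family: fixed}
  gdp_per_capita: 85698.00        # RMB, China 2022
  wtp_per_qaly: null              # null -> derived as 3 x gdp_per_capita
  dosing_year1_injections: 3      # day 1, day 90, day 270
  dosing_later_injections: 2      # every 6 months thereafter
  lab_visits_per_year: 2          # lipid-panel monitoring, both arms

transitions:
  mi_incidence_statin:  {baseline: 0.0234, low: 0.0187,  high: 0.0281,  family: beta}
  rr_mi_inclisiran:     {baseline: 0.68,   low: 0.48,    high: 0.96,    family: lognormal}
  p_revasc:             {baseline: 0.032,  low: 0.0256,  high: 0.0384,  family: beta}
  p_recurrence:         {baseline: 0.041,  low: 0.039,   high: 0.049,   family: beta}
  rehab_rate:           {baseline: 0.0996, low: 0.0797,  high: 0.1195,  family: beta}
  noncvd_mortality_rep: {baseline: 0.0042, low: 0.00336, high: 0.00504, family: beta}
  mi_mortality_at_ref:  {baseline: 0.105,  low: 0.084,   high: 0.126,   family: beta}
  post_mi_mortality:    {baseline: 0.021,  low: 0.0168,  high: 0.0252,  family: beta}
  # representative non-CVD death probability the life table is anchored to
  noncvd_mortality_ref: 0.0042
  # if true, MI-state death uses mi_mortality_at_ref as a flat probability
  # instead of (mi_mortality_at_ref / noncvd_mortality_ref) x q(age)
  mi_mortality_fixed: false
  # if true, post-MI death is the flat 2.1% even when background mortality
  # exceeds it at old ages (default takes max(q(age), 2.1%))
  post_mi_mortality_flat: false
  # apply the MI risk ratio to recurrent MI in the inclisiran arm as well
  rr_applies_to_recurrence: true

costs:   # RMB
  inclisiran_per_injection:  {baseline: 20000.00, low: 16000.00, high: 24000.00, family: gamma}
  injection_fee:             {baseline: 36.00, family: fixed}
  statin_daily:              {baseline: 3.45,  low: 2.76,   high: 4.14,   family: gamma}
  lab_fee_per_visit:         {baseline: 211.00, low: 168.80, high: 253.20, family: gamma}
  mi_hospitalization_annual: {baseline: 30381.30, low: 24305.04, high: 36457.56, family: gamma}
  revascularization:         {baseline: 68625.60, low: 59400.48, high: 82350.72, family: gamma}
  rehab_first_year:          {baseline: 18758.50, low: 15006.00, high: 22510.00, family: gamma}
  rehab_later_years:         {baseline: 10800.00, low: 8540.00,  high: 12960.00, family: gamma}
  exchange_rate_rmb_per_usd: 6.7261   # 2022: USD 100.00 = RMB 672.61
  cpi_factor_to_2023: 1.0             # medical-care CPI multiplier (config-exposed)

utilities:
  u_pre_mi:         {baseline: 0.84, low: 0.73, high: 0.95, family: beta}
  u_post_event:     {baseline: 0.80, low: 0.69, high: 0.91, family: beta}
  dec_recurrent_mi: {baseline: 0.06, family: beta}   # bounds default to +/-20%
  dec_revasc:       {baseline: 0.07, family: beta}

sensitivity:
  seed: 20240226
  n_psa: 1000
  range_to_sd_divisor: 3.92   # printed bounds treated as a 95% interval; 4.0 also accepted
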
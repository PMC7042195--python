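# Base-case configuration for the MRI screening cost-effectiveness model.
# All monetary values are 2018 USD. Probabilities and utility weights are
# dimensionless fractions; hazard ratios are relative to general-population
# mortality; annual costs apply from the model start age (6 y) onward.
parameters:
  prevalence_asd: 0.15          # ASD prevalence among high-risk infant siblings
  sens_mri_6: 0.82              # MRI screening sensitivity at 6 months
  sens_mri_12: 0.88             # MRI screening sensitivity at 12 months
  spec_mri_6: 1.00              # MRI screening specificity at 6 months
  spec_mri_12: 0.95             # MRI screening specificity at 12 months
  p_early_intervention: 0.62    # status-quo chance of receiving EI before age 4
  p_id_without_ei: 0.37         # P(intellectual disability | ASD, no EI)
  rr_id_with_ei: 0.61           # risk ratio of ID given EI before age 4
  hr_asd: 2.18                  # mortality hazard ratio, ASD without ID
  hr_asd_id: 5.78               # mortality hazard ratio, ASD with ID
  qol_asd: 0.68                 # utility weight, ASD without ID
  qol_asd_id: 0.46              # utility weight, ASD with ID
  cost_mri: 1814.0              # one-time cost of an MRI screen
  cost_ei: 148367.0             # one-time cost of 2 years of early intervention
  discount_rate: 0.03           # annual discount rate for costs and QALYs
  qol_decline_per_year: 0.0     # adult per-year utility decrement (disabled)
  qol_decline_start_age: 18     # age at which the adult decline would begin
  discount_upfront_to_birth: false

# Annual ASD-related cost streams by outcome class and age band (societal
# totals; the non-ASD class incurs no ASD-related annual cost by assumption).
cost_schedule:
  asd_only:
    ages_6_17: 58526.0
    ages_18_21: 69889.0
    ages_22_plus: 54154.0
  asd_id:
    ages_6_17: 95983.0
    ages_18_21: 127718.0
    ages_22_plus: 96247.0

# Cost-accounting perspectives. annual_cost_fraction is the share of each
# societal annual cost stream borne by the perspective; both narrower
# perspectives bear 100% of the direct early-intervention and screening costs.
perspectives:
  societal:     {annual_cost_fraction: 1.00, mri_share: 1.0, ei_share: 1.0}
  health_care:  {annual_cost_fraction: 0.23, mri_share: 1.0, ei_share: 1.0}
  educational:  {annual_cost_fraction: 0.12, mri_share: 1.0, ei_share: 1.0}

# Probabilistic-sensitivity-analysis distributions (moment-matched).
# Parameters absent here (test characteristics, all costs) are held fixed.
distributions:
  prevalence_asd:       {family: beta,  mean: 0.15, sd: 0.01}
  p_early_intervention: {family: beta,  mean: 0.62, sd: 0.07}
  p_id_without_ei:      {family: beta,  mean: 0.37, sd: 0.04}
  rr_id_with_ei:        {family: beta,  mean: 0.61, sd: 0.20}
  hr_asd:               {family: gamma, mean: 2.18, sd: 0.10}
  hr_asd_id:            {family: gamma, mean: 5.78, sd: 0.46}
  qol_asd:              {family: beta,  mean: 0.68, sd: 0.23}
  qol_asd_id:           {family: beta,  mean: 0.46, sd: 0.17}

# One-way sensitivity ranges (low, high).
ranges:
  prevalence_asd:            [0.01, 0.19]
  sens_mri_6:                [0.48, 0.97]
  sens_mri_12:               [0.48, 0.97]
  spec_mri_6:                [0.90, 1.00]
  spec_mri_12:               [0.90, 1.00]
  p_early_intervention:      [0.48, 0.76]
  p_id_without_ei:           [0.10, 0.63]
  rr_id_with_ei:             [0.32, 1.00]
  hr_asd:                    [2.00, 2.38]
  hr_asd_id:                 [4.94, 6.95]
  qol_asd:                   [0.47, 0.70]
  qol_asd_id:                [0.34, 0.58]
  cost_mri:                  [1288.0, 2464.0]
  cost_ei:                   [112958.0, 183777.0]
  annual_cost_scale_asd:     [0.75, 1.25]
  annual_cost_scale_asd_id:  [0.75, 1.25]
  discount_rate:             [0.01, 0.05]

run:
  perspective: societal
  wtp: [50000.0, 100000.0]
  psa_n: 10000
  seed: null          # must be set (config or --seed) before a PSA will run
  start_age: 6
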
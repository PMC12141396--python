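# Packaged base-case configuration.
#
# Clinical inputs (response-category counts at month 6, out of 58 per arm)
# come from the matched-cohort comparison this package models; economic
# inputs are the package's calibrated base case: Chinese post-procurement
# drug pricing, HAQ-linear state costs and utilities, 5%/year discounting,
# willingness-to-pay at 3x per-capita GDP (CNY).

cohort:
  n_per_arm: 100
  seed: 2020
  response_counts:
    TOF: {ACR70: 20, ACR50: 11, ACR20: 11, NONE: 16}
    ADA: {ACR70: 22, ACR50: 12, ACR20: 11, NONE: 13}

matching:
  covariates: [age, female, bmi, duration, sjc28, tjc28, stiffness_min,
               vas, esr, crp, das28, rf, haq]
  caliper_sd: 0.2
  order: descending

efficacy:
  auxiliary_measures: [vas, haq, esr, crp]

model:
  cycle_length: 0.5        # years
  horizon: 27.0            # years (ages 51-78)
  start_age: 51.0
  end_age: 78.0
  discount_rate_costs: 0.05
  discount_rate_qalys: 0.05
  mortality_per_cycle: 0.005
  wtp_per_qaly: 257094.0   # 3 x per-capita GDP, CNY
  currency: "¥"
  half_cycle_correction: false
  arms:
    tof:
      drug_cost_per_cycle: 1500.0
      response_counts: {ACR70: 20, ACR50: 11, ACR20: 11, NONE: 16}
      delta_haq: {ACR70: 0.60, ACR50: 0.55, ACR20: 0.0}
      baseline_haq: 0.60
      haq_progression_per_year: 0.035
      withdrawal_per_cycle: 0.04
      palliative_drug_cost_per_cycle: 400.0
      state_cost_base_per_cycle: 1500.0
      state_cost_per_haq_per_cycle: 3000.0
      utility: {intercept: 0.862, slope: 0.327, floor: 0.30}
      nonmedical_cost_per_cycle: 600.0
      indirect_cost_per_cycle: 40.0
      sae_disutility_per_cycle: 0.0
    ada:
      drug_cost_per_cycle: 19500.0
      response_counts: {ACR70: 22, ACR50: 12, ACR20: 11, NONE: 13}
      delta_haq: {ACR70: 0.60, ACR50: 0.55, ACR20: 0.0}
      baseline_haq: 0.60
      haq_progression_per_year: 0.035
      withdrawal_per_cycle: 0.065
      palliative_drug_cost_per_cycle: 400.0
      state_cost_base_per_cycle: 1500.0
      state_cost_per_haq_per_cycle: 3000.0
      utility: {intercept: 0.862, slope: 0.327, floor: 0.30}
      nonmedical_cost_per_cycle: 600.0
      indirect_cost_per_cycle: 40.0
      sae_disutility_per_cycle: 0.0

sensitivity:
  tornado:
    rel_change: 0.10
  psa:
    n_iterations: 5000
    seed: 2024
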
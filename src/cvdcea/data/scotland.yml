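# Base-case configuration, Scottish prices (GBP).
schema: cvdcea-config-v1
region: Scotland
price_year: 2026
coefficients: coefficients.yml

discount_rate: 0.035
discount_rate_range: [0.015, 0.055]   # one-way DSA bounds
wtp_threshold: 20000
risk_threshold: 20

options:
  apply_hdl_shift: true
  events_include_fatal: true
  time_scale: entry
  sample_coefficients: false

# relative risk per 1.0 mmol/L reduction in non-HDL cholesterol
rr_per_mmol:
  nonfatal_chd: {mean: 0.77, ci: [0.75, 0.80], family: beta}
  nonfatal_cbvd: {mean: 0.87, ci: [0.83, 0.91], family: beta}
  fatal_cvd: {mean: 0.90, ci: [0.86, 0.92], family: beta}
  any_cvd: {mean: 0.79, ci: [0.77, 0.81], family: beta}   # stored; not used by default

shared_costs:
  monitoring_first_year: {mean: 102.51, ci: [63.51, 141.51], family: gamma}
  monitoring_subsequent: {mean: 55.48, ci: [16.48, 94.48], family: gamma}
  risk_assessment: {mean: 17.68, ci: [10.68, 24.68], family: gamma}
  diabetes_annual: {mean: 314.33, ci: [156.50, 469.50], family: gamma}

pill_disutility: {mean: 0.002, ci: [0.000, 0.004], family: beta}

interventions:
  - name: "No intervention"
    active: false
  - name: "Statins"                     # atorvastatin 20 mg/day
    nonhdl_reduction: {mean: 26.0, ci: [15.0, 35.0], family: beta}
    hdl_increase: {mean: 4.0, ci: [0.0, 8.0], family: beta}
    diabetes_ari: {mean: 0.50, ci: [0.1, 1.0], family: lognormal}
    drug_cost: {mean: 13.44, ci: [8.99, 23.99], family: gamma}
  - name: "Berberine"                   # berberine 1000 mg/day
    nonhdl_reduction: {mean: 16.4, ci: [14.6, 18.2], family: beta}
    hdl_increase: {mean: 9.1, ci: [3.8, 14.4], family: beta}
    diabetes_ari: {mean: -4.6, ci: [-6.1, -4.2], family: lognormal}  # negated sampling
    drug_cost: {mean: 94.58, ci: [27.34, 424.86], family: gamma}
  - name: "Combined intervention 1"     # simvastatin 20 mg + berberine 1500 mg/day
    nonhdl_reduction: {mean: 34.4, ci: [33.1, 35.7], family: beta}
    hdl_increase: {mean: 25.0, ci: [23.2, 26.8], family: beta}
    # mean-zero combined diabetes effect over its reported range; a lognormal
    # with zero mean is degenerate, so a mean-preserving scaled beta is used
    diabetes_ari: {mean: 0.0, ci: [-4.6, 0.5], family: beta}
    drug_cost: {mean: 150.86, ci: [50.00, 646.28], family: gamma}
  - name: "Combined intervention 2"     # simvastatin 20 mg + berberine 900 mg/day
    nonhdl_reduction: {mean: 44.6, ci: [35.8, 53.4], family: beta}
    hdl_increase: {mean: 17.4, ci: [8.6, 26.2], family: beta}
    diabetes_ari: {mean: 0.0, ci: [-4.6, 0.5], family: beta}
    drug_cost: {mean: 94.11, ci: [33.59, 391.36], family: gamma}

# synthetic-cohort generator overrides (defaults live in cvdcea.cohort)
generator: {}
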
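# Shared regression coefficient tables.
#
# provenance: placeholder — these are plausible stand-in values calibrated so
# that the synthetic eligible pool shows realistic Scottish event rates and
# eligibility fractions.  They are NOT the published regression estimates
# (which live in supplementary tables of the source model); replace them and
# set provenance: published to run with the real tables.
provenance: placeholder

assign:
  # 10-year risk = 100 * (1 - baseline_survival ** exp(LP - lp_mean))
  female:
    baseline_survival: 0.930
    lp_mean: 8.0677
    coefficients:
      age: 0.09133
      sbp: 0.01288
      tc: 0.16393
      hdl: -0.60888
      cigs_per_day: 0.03044
      diabetes: 0.99529
      family_history_cvd: 0.52692
      simd: 0.01522
  male:
    baseline_survival: 0.885
    lp_mean: 7.5612
    coefficients:
      age: 0.08431
      sbp: 0.01229
      tc: 0.15222
      hdl: -0.56205
      cigs_per_day: 0.02810
      diabetes: 0.87820
      family_history_cvd: 0.46837
      simd: 0.01405

gompertz_primary:
  # cause-specific first-event hazards from the CVD-free state;
  # h(t) = exp(beta.x) * exp(gamma t), t in years since model entry,
  # attained age enters through the age covariate (updated annually)
  nonfatal_chd:
    gamma: 0.010
    covariates:
      intercept: -11.80
      age: 0.0740
      male: 0.3200
      sbp: 0.0085
      tc: 0.1400
      hdl: -0.4200
      cigs_per_day: 0.0180
      diabetes: 0.6000
      family_history_cvd: 0.2500
      simd: 0.0100
  nonfatal_cbvd:
    gamma: 0.010
    covariates:
      intercept: -12.60
      age: 0.0800
      male: 0.1800
      sbp: 0.0110
      tc: 0.0500
      hdl: -0.2000
      cigs_per_day: 0.0160
      diabetes: 0.5000
      family_history_cvd: 0.1500
      simd: 0.0100
  fatal_cvd:
    gamma: 0.010
    covariates:
      intercept: -13.20
      age: 0.0950
      male: 0.3500
      sbp: 0.0100
      tc: 0.1000
      hdl: -0.3500
      cigs_per_day: 0.0200
      diabetes: 0.7000
      family_history_cvd: 0.2000
      simd: 0.0120
  noncvd_death:
    gamma: 0.010
    covariates:
      intercept: -10.60
      age: 0.0900
      male: 0.2500
      sbp: 0.0000
      tc: 0.0000
      hdl: 0.0000
      cigs_per_day: 0.0220
      diabetes: 0.3000
      family_history_cvd: 0.0000
      simd: 0.0120

gompertz_secondary:
  # all-cause mortality after a non-fatal first event;
  # timescale: years since the event
  post_chd:
    gamma: 0.080
    covariates:
      intercept: -8.60
      age_at_event: 0.0850
      simd: 0.0060
      family_history_cvd: 0.1000
  post_cbvd:
    gamma: 0.080
    covariates:
      intercept: -8.20
      age_at_event: 0.0850
      simd: 0.0060
      family_history_cvd: 0.1000

probit_secondary:
  # recurrent (secondary) CVD event probability per cycle in chronic states
  intercept: -2.30
  age_at_event: 0.0080
  simd: 0.0040
  family_history_cvd: 0.1500

utility:
  # SF-12-style utility regression: baseline by sex and attained age,
  # event decrements for the chronic states
  intercept: 0.9100
  male: 0.0150
  age: -0.0028      # per year of age over 40
  age2: -0.000020   # per squared year over 40
  event_decrements:
    post_chd: 0.0650
    post_cbvd: 0.1150
  recurrent_event_decrement: 0.0500

cost:
  # annual hospitalization-cost regressions (GBP); natural cubic splines
  # capture non-linearity over time
  pre_event:
    intercept: 140.0
    coefficients:
      age_at_entry: 4.0    # per year of age over 40 at model entry
      simd: 1.2
      family_history_cvd: 15.0
    spline:
      knots: [0.0, 10.0, 20.0, 35.0, 65.0]
      coefficients: [4.24537, 0.490509, -0.840278, 0.354398]
  post_event:
    post_chd:
      # intercept is the acute post-event year; the spline decays to a
      # chronic management level (~700-1000/yr) rising again late
      intercept: 3200.0
      coefficients:
        age_at_event: 9.0   # per year of age over 40 at the event
        simd: 2.0
        family_history_cvd: 25.0
      spline:
        knots: [0.0, 1.0, 3.0, 10.0, 40.0]
        coefficients: [-1927.17155, 9086.861981, -13416.571293, 4361.992002]
    post_cbvd:
      intercept: 4300.0
      coefficients:
        age_at_event: 11.0
        simd: 2.4
        family_history_cvd: 25.0
      spline:
        knots: [0.0, 1.0, 3.0, 10.0, 40.0]
        coefficients: [-2607.011007, 12280.440293, -18126.537857, 5888.277706]
  recurrent_event_cost: 2200.0
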
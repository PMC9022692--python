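# SYNTHETIC survival parameters (default).
#
# Gompertz baseline hazards and covariate log-hazard-ratios with
# UK-plausible magnitudes; NOT fitted estimates from any cohort.
# Supply real fitted values through the same structure (the 'survival'
# section of a run configuration; see statincea.config).
max_age: 110.0
causes:
  nonfatal_chd:
    baseline:
      rate_at_ref: 0.004
      gamma: 0.075
      ref_age: 60.0
    coefficients:
      male: 0.45
      diabetes: 0.6
      sbp: 0.012
      tc: 0.18
      hdl: -0.45
      cpd: 0.022
      simd: 0.008
      famhist: 0.25
    reference:
      sbp: 130.0
      tc: 5.5
      hdl: 1.4
      simd: 20.0
  nonfatal_cbvd:
    baseline:
      rate_at_ref: 0.002
      gamma: 0.085
      ref_age: 60.0
    coefficients:
      male: 0.25
      diabetes: 0.5
      sbp: 0.016
      tc: 0.08
      hdl: -0.25
      cpd: 0.018
      simd: 0.008
      famhist: 0.15
    reference:
      sbp: 130.0
      tc: 5.5
      hdl: 1.4
      simd: 20.0
  fatal_cvd:
    baseline:
      rate_at_ref: 0.0015
      gamma: 0.1
      ref_age: 60.0
    coefficients:
      male: 0.5
      diabetes: 0.65
      sbp: 0.014
      tc: 0.15
      hdl: -0.4
      cpd: 0.025
      simd: 0.01
      famhist: 0.2
    reference:
      sbp: 130.0
      tc: 5.5
      hdl: 1.4
      simd: 20.0
  fatal_noncvd:
    baseline:
      rate_at_ref: 0.006
      gamma: 0.092
      ref_age: 60.0
    coefficients:
      male: 0.25
      diabetes: 0.3
      hdl: -0.1
      cpd: 0.02
      simd: 0.012
    reference:
      sbp: 130.0
      tc: 5.5
      hdl: 1.4
      simd: 20.0
post_event_mortality:
  chd:
    rate_at_ref: 0.06
    gamma: 0.07
    ref_age: 60.0
  cbvd:
    rate_at_ref: 0.08
    gamma: 0.07
    ref_age: 60.0
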
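# Demo run configuration (SYNTHETIC parameters throughout).
#
# The cohort, survival, utility and cost values exercised by this file
# are synthetic UK-plausible magnitudes shipped with the package; they
# are not fitted estimates.  Real parameter sets can be supplied via
# the same keys (see statincea.config).
n: 2000
seed: 7
psa_iterations: 50
wtp: 20000
wtp_grid:
  lo: 0
  hi: 50000
  step: 500
risk_thresholds: [0.20, 0.10]
cohort: {}        # CohortSpec field overrides
treatment: {}     # TreatmentParams field overrides
econ: {}          # EconParams field overrides
scenario: null
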
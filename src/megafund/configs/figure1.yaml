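# Default validation-sweep setup: a 200-asset pool, half lemons,
# simulated over 12 semesters at 20,000 paths per point.  The sweep runs
# all three behaviors over the validation grid.
simulation:
  n_assets: 200
  lemon_fraction: 0.5
  n_paths: 20000
  seed: 1
  horizon_semesters: 12
  investment_per_program: 0.2
  senior_share: 0.5
  senior_rate: 0.085
  cash_rate_semester: 0.01
  waterfall_mode: recovery

structuring:
  behavior: reliable
  validation_fraction: 0.0
  toxic_fraction: 0.25
  detection_scale: 10.0
  false_positive_rate: 0.0
  uplift_slope: 1.0

dynamics:
  lemon_severity: 2.0
  nonlemon_matrix:
    preclinical_advance: 0.12
    preclinical_fail: 0.22
    phase1_advance: 0.10
    phase1_fail: 0.22
  costs:
    upfront: 0.1
    periodic:
      preclinical: 0.005
      phase1: 0.01
    milestone:
      phase1: 0.02
      sold: 0.05
    sale_value: 12.3

sweep:
  v_grid: [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3]
  behaviors: [ideal, reliable, unfair]
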
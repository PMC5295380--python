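# The twelve worked closed-form cases: reliable funds with and without
# lemons, ideal (lemon-free) funds, and unfair funds whose toxic SPVs
# concentrate 43 of the 52 slots on lemons.  All amounts in millions.
#
# Note: the multi-SPV senior results are M-invariant, so the M used for
# the D=52 cases (5 SPVs) only needs M*D >= N.
defaults:
  n_assets: 150
  investment_per_program: 0.2
  success_value: 12.3
  senior_share: 0.5
  horizon_years: 10

cases:
  reliable_1:
    n_lemons: 0
    success_prob: 0.05
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.038
  reliable_2:
    n_lemons: 0
    success_prob: 0.05
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.05
  reliable_3:
    n_lemons: 0
    success_prob: 0.05
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.085
  reliable_4:
    n_lemons: 0
    success_prob: 0.05
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.094
  reliable_5:
    n_lemons: 75
    success_prob: 0.10
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.085
  reliable_6:
    n_lemons: 75
    success_prob: 0.10
    n_spvs: 5
    spv_size: 52
    senior_rate: 0.085
  reliable_7:
    n_lemons: 75
    success_prob: 0.10
    n_spvs: 5
    spv_size: 52
    senior_rate: 0.168
  ideal_1:
    n_lemons: 0
    success_prob: 0.10
    n_spvs: 1
    spv_size: 150
    senior_rate: 0.168
  ideal_2:
    n_lemons: 0
    success_prob: 0.10
    n_spvs: 5
    spv_size: 52
    senior_rate: 0.086
  ideal_3:
    n_lemons: 0
    success_prob: 0.10
    n_spvs: 5
    spv_size: 52
    senior_rate: 0.168
  unfair_r086:
    n_lemons: 75
    success_prob: 0.10
    n_spvs: 6
    spv_size: 52
    senior_rate: 0.086
    unfair:
      n_clean_spvs: 3
      n_toxic_spvs: 3
      lemons_per_clean_spv: 9
      lemons_per_toxic_spv: 43
  unfair_r168:
    n_lemons: 75
    success_prob: 0.10
    n_spvs: 6
    spv_size: 52
    senior_rate: 0.168
    unfair:
      n_clean_spvs: 3
      n_toxic_spvs: 3
      lemons_per_clean_spv: 9
      lemons_per_toxic_spv: 43
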
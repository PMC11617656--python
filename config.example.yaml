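# Example configuration for `terpene-budget run --config config.example.yaml`.
# Every key is optional; omitted keys use the documented defaults.

input_mode: synthetic     # or "file" with cohort_path/terpenes_*_path
convention: printed       # girdle correction: printed | add_back_absolute
maintenance: auto         # "auto" (girdled-tree mean drawdown) or a percent
nsc_pool: total_nsc       # total_nsc | total_sugar
n_perm: 999
seed: 0

generator:
  n_watered: 14
  n_mild: 16
  n_moderate: 16
  psi_range_watered: [-0.91, -0.31]
  psi_range_mild: [-2.85, -1.66]
  psi_range_moderate: [-3.61, -2.86]
  induction_slope: 15.9            # mg g^-1 per MPa
  watered_induction_mean: 49.3     # mg g^-1
  girdle_loss_anchors: [[-0.31, -0.43], [-3.61, 0.0]]
  sugar_pre_mean: 5.4              # % DW
  sugar_pre_sd: 1.4
  chamber_temp_mean: 305.0         # K
  n_missing_post: 4

energy:
  atp_per_glucose: 32
  nadph_per_glucose_opp: 12
  po_ratio_nadh: 2.5
  ctp_atp_equiv: 2
  reductant_per_2e_step: 1
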
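min_len: 50
max_len: 100
cationic:
  H_min: 0.0
  H_max: 0.6
  muH_min: 0.1
  muH_max: 1.0
  z_min: 3
  z_max: 10
  min_polar: 6
  min_uncharged_STNQH: 1
  min_gly: 0
  max_charged: 12
  forbid_cys: true
  window_len: 18
anionic:
  H_min: -0.7
  H_max: 0.4
  muH_min: 0.0
  muH_max: 0.5
  z_min: -10
  z_max: -3
  min_polar: null
  min_uncharged_STNQH: null
  min_gly: null
  max_charged: null
  forbid_cys: true
  window_len: 18
helicity:
  method: propensity
  min_helix_frac: 0.5
  min_mean_propensity: 1.03
aggregation:
  window: auto
  end_mode: truncate
  gate_lo: -30.0
  gate_hi: 30.0
  target: segment
predictors:
  signal_mode: heuristic
  signal_path: null
  tm_mode: heuristic
  tm_path: null
  localization_mode: passthrough
  localization_path: null
  secreted_classes:
  - extracellular
  - secreted
pwm_core_cutoff: 0.75
pwm_matrix_cutoff: 0.8
polar_set: DEHKNQRSTY
hydrophobicity_scale: fauchere_pliska
a3v_scale: aggrescan_a3v
seed: 0
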
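seed: 0
n_patients: 20
timepoints: [D1, D8]
imaging: true
write_images: false
scene:
  image_height_px: 256
  image_width_px: 256
patient_model:
  mean_single_epithelial: 2.0
  mean_single_mesenchymal: 2.0
  n_pbmc: 25
  cluster_prob: 0.45
  cluster_size_range: [2, 4]
calibration: default
survival:
  endpoints:
    OS: {dist: exponential, rate_per_month: 0.06}
    PFS: {dist: exponential, rate_per_month: 0.25}
  log_hazard_ratios:
    has_cluster_mctc: 1.638
  censoring_rate: 0.3
  followup_horizon_months: 60.0
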
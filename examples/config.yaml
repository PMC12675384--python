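# Full-pipeline configuration: synthetic cohort -> extraction -> fits -> partition
simulate:
  n_participants: 8
  noise_sd: 0.2          # within-series measurement noise, degC
  participant_spread: 0.5  # SD of per-participant vertical offset, degC
  seed: 42

fit:
  multi_start: true

thermo:
  W_stride_kJ: -0.0034   # net foot work per stride (negative = dissipation)
  m_foot_kg: 1.17
  c_foot_kJ_per_kgK: 1.96
  total_strides: 1674
  duration_min: 30.0
  W_bounds: [-0.0071, 0.00023]  # mean +/- 1 SD of net work
  c_bounds: [1.31, 3.62]        # bone .. blood specific heat

burn:
  baseline_C: 30.0
  threshold_C: 43.3
  speed_m_per_s: 1.25
  mode: mechanical_only
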
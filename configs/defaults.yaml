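# Complete default analysis configuration (mirrors mepdecode.defaults).
# Every constant below is the fixed value used by the decoding protocol;
# overrides passed via --config are echoed into run logs and hashed into
# output metadata.

montage:  # 28 retained channels (TP9/TP10 excluded)
  [FP1, FP2, F3, F4, C3, C4, P3, P4, O1, O2,
   F7, F8, T7, T8, P7, P8, Fz, Cz, Pz, Iz,
   FC1, FC2, CP1, CP2, FC5, FC6, CP5, CP6]

bands:  # Hz; power averaged per band per channel -> 168 features
  broadband: [4, 100]     # excluding line-noise bins inside (58, 62)
  theta: [4, 7]
  alpha: [8, 12]
  beta: [13, 35]
  low_gamma: [36, 58]
  high_gamma: [62, 100]
line_noise_excluded_hz: [58, 62]

windows_s_before_tms:  # six 500-ms pre-stimulus analysis windows
  - [3.005, 2.505]
  - [2.505, 2.005]
  - [2.005, 1.505]
  - [1.505, 1.005]
  - [1.005, 0.505]
  - [0.505, 0.005]

downsampled_rate_hz: 500
spectrum: {fmin_hz: 4.0, fmax_hz: 100.0, resolution_hz: 0.25}

grid:
  n_lambda: 100           # linearly spaced in [1e-10, 1]
  lambda_min: 1.0e-10
  lambda_max: 1.0
  feature_counts: 1..168  # top-n ranked features, n = 1..168

cv: {k: 5, stratified: true}
permutation_reps: 500     # null grid searches; 95th-percentile threshold

emg:
  segment_s_post_tms: [0.020, 0.100]
  mep_window_s_post_tms: [0.020, 0.040]
  offset_window_s_pre_tms: [0.020, 0.001]
  prestim_rms_window_s_pre_tms: [0.105, 0.005]
  rms_quantile: 0.75
  rms_iqr_multiplier: 3.0
  corr_threshold: 0.4
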
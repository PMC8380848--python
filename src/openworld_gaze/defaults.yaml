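# Versioned default configuration: the calibrated synthetic-study conditions.
n_subjects:
  humvee: 15
  motorcycle: 14
  aircraft: 9
  furniture: 7
master_seed: 1
environment:
  path_length_m: 2000.0
  n_targets_per_condition: 15
  n_other: 166
  n_trail_markers: 19
  lateral_offset_sd_m: 6.0
  placement_jitter: 0.35
  surface_area:
    humvee:
    - 22.0
    - 0.15
    motorcycle:
    - 2.8
    - 0.2
    aircraft:
    - 35.0
    - 0.5
    furniture:
    - 3.5
    - 0.7
    other:
    - 8.0
    - 1.0
    trail_marker:
    - 0.5
    - 0.1
  visibility_coeff: 30.0
  visibility_exponent: 0.15
  visibility_min_m: 25.0
  visibility_max_m: 90.0
navigation:
  mean_duration_s: 680.0
  sd_duration_s: 40.0
  speed_noise_sd: 0.12
  speed_noise_tau_s: 5.0
  eye_height_m: 1.7
  math_onset_s: 480.0
  dual_task_speed_multiplier: 0.76
  math_n_trials: 3
  math_numbers_per_trial:
  - 3
  - 4
  math_number_audio_s: 1.0
  math_pause_range_s:
  - 3.0
  - 4.0
  math_response_s: 4.0
  math_break_range_s:
  - 8.0
  - 30.0
gaze:
  sampling_rate_hz: 300.0
  fixation_median_s: 0.3
  fixation_sigma: 0.68
  fixation_max_s: 4.0
  short_fixation_prob: 0.1
  position_noise_sd_deg: 0.03
  drift_speed_max_deg_s: 3.0
  saccade_d0_s: 0.02
  saccade_d1_s_per_deg: 0.0022
  saccade_dur_jitter: 0.1
  saccade_dur_range_s:
  - 0.012
  - 0.09
  new_target_amp_median_deg: 5.0
  new_target_amp_sigma: 0.6
  refix_amp_median_deg: 1.3
  refix_amp_sigma: 0.5
  amp_range_deg:
  - 0.3
  - 25.0
  angle_horizontal_weight: 0.7
  angle_horizontal_sd_deg: 25.0
  gaze_extent_x_deg: 18.0
  gaze_extent_y_deg: 7.0
  blink_prob_per_boundary: 0.14
  blink_median_s: 0.15
  blink_sigma: 0.45
  blink_range_s:
  - 0.06
  - 0.45
  dropout_short_prob: 0.01
  dropout_short_range_s:
  - 0.01
  - 0.04
  dropout_long_prob: 0.01
  dropout_long_range_s:
  - 0.6
  - 2.0
  background_prob: 0.505
  background_burst_mean: 5.2
  terrain_share: 0.8
  area_exponent: 0.15
  distance_decay_m: 70.0
  burst_mean: 5.8
  target_weight_mult: 1.05
  target_inspection_prob: 0.93
  target_burst_mult: 1.25
  target_dwell_factor: 0.955
  target_distance_decay_m: 60.0
  contamination_prob: 0.05
  terrain_distance_median_m: 25.0
  sky_distance_m: 1000.0
  math_blink_mult: 1.48
  math_burst_mult: 0.7
  math_target_switch_mult: 1.0
detection:
  velocity_factor: 6.0
  min_saccade_dur: 0.012
  min_fixation_dur: 0.05
  qualifying_fixation_dur: 0.1
  blink_gap_range:
  - 0.05
  - 0.5
  velocity_window: 5
  qc_saccade_dur_range:
  - 0.012
  - 0.1
  qc_peak_vel_range:
  - 25.0
  - 1200.0
  threshold_floor: 5.0
  median_estimator: dispersion
labeling:
  dominance_threshold: 0.1
  exclude_classes:
  - terrain
  - sky
  count_invalid_in_denominator: true
  dominance_among_excluded: false
  sweep_thresholds:
  - 0.0
  - 0.01
  - 0.1
  - 0.2
  - 0.5
metrics:
  dropout_exclusion_frac: 0.25
  timeout_s: 1200.0
  min_validated_targets: 10
  outlier_sd: 3.0
  normalized_sign: subject_minus_global
tolerances:
  t1:
  - 0.27
  - 0.33
  t2:
  - 1.86
  - 2.26
  t3:
  - 6.1
  - 8.1
  t4:
  - 2.3
  - 2.9
  t5:
  - 42.0
  - 52.0
  t6:
  - 37.0
  - 57.0
  t7:
  - 31.0
  - 51.0
  t8:
  - 19.0
  - 29.0
  t9:
  - 36.0
  - 56.0
  t10:
  - 15.0
  - 15.0
  t11:
  - 19.0
  - 19.0
  t12:
  - 166.0
  - 166.0
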
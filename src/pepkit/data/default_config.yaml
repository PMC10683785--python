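generator:
  eeg_sampling_rate: 1000.0
  channels:
  - Fz
  - Cz
  - L5
  - L6
  - L7
  - R5
  - R6
  - R7
  pep_latency_ms:
  - 90.0
  - 130.0
  pep_duration_ms: 130.0
  pep_base_amplitude:
    Fz: 6.0
    Cz: 7.0
    mastoid: 3.6
  condition_gain:
    Fz: 1.04
    Cz: 1.03
    mastoid: 1.27
  age_gain:
    Fz: 1.0
    Cz: 1.25
    mastoid: 1.25
  elder_male_mastoid_gain: 1.8
  first_trial_gain: 2.0
  amplitude_jitter_sigma: 0.25
  subject_gain_sigma: 0.25
  noise_alpha: 1.0
  noise_rms:
    Fz: 2.2
    Cz: 2.6
    mastoid: 1.2
  line_noise_amplitude: 2.0
  line_noise_freq: 60.0
  accel_noise_rms: 0.01
  platform:
    sampling_rate: 150.0
    peak_acceleration: 1.9620000000000002
    target_displacement: 0.2
    target_peak_velocity: 1.0
  pre_roll_s: 3.0
  inter_onset_s: 8.0
  post_roll_s: 2.0
  n_per_cell: 10
  dropout_events: 40
  seed: 0
filter:
  bandpass_order: 2
  bandpass_low: 2.5
  bandpass_high: 30.0
  notch_freq: 60.0
  notch_quality: 30.0
onset:
  baseline_window_s: 1.0
  threshold_k: 5.0
  min_consecutive_samples: 3
  search_window_s: 1.0
channels:
- Cz
- Fz
- mastoid
divide_by_sd: true
make_figures: true
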
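model:
  N: 1200
  S: 300
  p: 0.5
  tau: 5.0
  g: 1.0
  k: 0.2
  alpha: 100.0
  I: 26
  O: 3
  dt: 1.0
  force_interval: 2
  x0_jitter: 0.1
  shared_support: false
teaching:
  beta: 3.0
  gamma: 0.5
  T: 15000.0
  delta: 0.5
  sigma_floor: 1.0e-06
  hebb_eta: 0.0001
stimulus:
  alphabet: abcdefghijklmnopqrstuvwxyz
  letter_slot_ms: 50.0
  pulse_fraction: 0.8
  pulse_amplitude: 8.0
  image_size: 60
  sections: 10
  window_cols: 6
  image_gain: 8.0
  dt: 1.0
  noise_image_mean: 0.5
  noise_image_sd: 0.25
  image_noise_sd: 0.0
schedule:
  C: 2200
  chunk_probabilities:
  - 0.3333333333333333
  - 0.3333333333333333
  - 0.3333333333333333
  use_separators: true
  m: 0.0
  d: 0.0
  delayed_modality: 2
  seed: 0
variant: original
C_test: null
m: 0.0
d: 0.0
manipulate: train
window_sd: 20.0
no_response_threshold: 0.3
epoch_statistic: mean
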
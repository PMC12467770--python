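# Desk-scale default run configuration. Every numeric default of the
# pipeline lives here; the library dataclasses mirror these values.
seed: 0
out_dir: runs/default
split_proportions: [0.7, 0.15, 0.15]

cohort:
  n: 2000
  seed: 0
  age_mean: 62.0
  age_sd: 14.0
  age_range: [18.0, 95.0]
  sex_p: 0.5
  ivsdd: [0.85, 0.004, 0.10, 0.22]
  lvpwdd: [0.82, 0.004, 0.08, 0.20]
  lvidd: [4.80, -0.005, 0.25, 0.45]
  ivsdd_threshold: [1.35, 1.45]
  lvpwdd_threshold: [1.30, 1.40]

render:
  size: 64
  base_inner_radius: 10.0
  base_thickness: 4.0
  base_silhouette: 26.0
  thickness_gain: 2.2
  inner_radius_gain: 2.0
  silhouette_gain: 2.0
  sex_asymmetry: 0.25
  exposure_sd: 0.18
  offset_sd: 0.06
  noise_sd: 0.08
  ring_intensity: 0.85
  interior_intensity: 0.35
  silhouette_intensity: 0.18

backbone:
  family: conv
  input_size: 64
  conv_channels: [16, 32, 64]
  conv_blocks: 1
  conv_head: [128, 64]
  dropout: 0.3
  freeze_encoder: true

train:
  learning_rate: 1.0e-3
  weight_decay: 1.0e-5
  epochs: 10
  batch_size: 32
  seed: 0
  schedule: constant
  warmup_frac: 0.05
  early_stop_patience: null

mine_net:
  hidden_sizes: [256, 64]
  activation: elu
  init_scheme: xavier

mine_train:
  learning_rate: 1.0e-3
  batch_size: 100
  max_epochs: 200
  ema_decay: 0.99
  n_seeds: 10
  plateau_patience: 20
  standardize_inputs: true
  min_delta: 1.0e-3

eval:
  n_boot: 500
  stages: [early, mid, final]
  attributes: [age, sex, IVSDd, LVPWDd, LVIDd]
  expected_ranking: []
  profile_split: test
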
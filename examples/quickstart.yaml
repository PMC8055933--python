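cohort:
  n_subjects: 10
  volume_shape: [28, 28, 28]
  n_contrasts: 6
  informative_set: [0, 3]
  lesion_effect: [-1.5, 0.0, 0.0, -1.5, 0.0, 0.0]
  cross_corr: 0.6
  n_lesions_range: [1, 2]
  lesion_radius_range: [2, 3]
patches:
  density: 0.05
architecture:
  n_filters: 8
  hidden_dim: 8
  attn_dim: 4
training:
  batch_size: 32
  learning_rate: 3.0e-3
  max_epochs: 6
  early_stop_patience: 6
  scheduler_patience: 3
  n_folds: 2
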
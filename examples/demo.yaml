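seed: 7
n_splits: 2
model:
  backbone: small_cnn
  pooling: attention
  lr: 0.01
  epochs: 20
  bag_size: 20
tiles_per_sample: 6
synthetic:
  n_samples_per_class: 16
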
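# Full-size defaults for `scintiseg train --config ...`.
# Any value can be overridden on the command line: -o section.key=value

phantom:
  image_size: 256
  n_patients: 171
  lesions_per_image: [1, 3]
  small_radius_px: [1.5, 3.0]
  large_radius_px: [4.0, 8.0]
  background_rate: 20.0
  spine_rate: 60.0
  lesion_rate: 120.0
  confounder_rate: 120.0
  n_confounders: [0, 2]
  cluster_prob: 0.2
  seed: 42

generator:
  levels: 5
  base_channels: 64
  use_pyramid: true
  use_deep_supervision: true
  encoder_block_types: [cdc, msfe, msfe, msfe, msfe]
  decoder_block_type: rms
  input_normalization: per_image_max
  seed: 42

critic:
  layers: 6
  base_channels: 64
  input_mode: product      # product | concat | sum | mask_only

loss:
  alpha: 1.0
  beta: 1.0
  head_weights: [1.0, 1.0, 1.0, 1.0]
  seg_loss_kind: dice      # dice | bce | dice_plus_bce

train:
  lr: 0.0001
  optimizer: adam
  batch_size: 32
  epochs: 600
  seed: 42
  n_runs: 5
  use_gan: true
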
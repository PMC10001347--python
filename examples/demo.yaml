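# Desk-scale demo: full pipeline at 32x32 in about a minute on one CPU.
run_dir: demo_run
stages: [fixtures, gan, rsa, vit, eval]
fixtures:
  n_per_class: 12
  fake_fraction: 0.5
  size: 32
  seed: 11
gan:
  image_size: 32
  latent_dim: 64
  base_filters: 32
  epochs: 100
  batch_size: 32
  sample_every: 50
  seed: 12
rsa:
  n_per_class: 12
  use_gan_fakes: true
  seed: 13
vit:
  variant: ViT32/8
  embed_dim: 32
  depth: 2
  mlp_dims: [64, 32]
  epochs: 25
  batch_size: 10
  augment: false
  seed: 14
eval:
  seed: 15
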
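# Desk-scale settings trainable on one CPU in minutes: 2-lead / L=128
# synthetic records, 2-block / 32-channel model. The hotter beta_end keeps
# alpha_bar_T ~ e^-10 so sampling genuinely starts from noise at small T.
model:
  n_residual_layers: 2
  residual_channels: 32
  skip_channels: 32
  diff_embed_dims: [32, 64, 64]
  label_dim: 2
  signal_channels: 2
  spade: {d_model: 32, window: 8, n_heads: 4, d_ffn: 64, ssm_state_dim: 16}
schedule: {T: 100, beta_start: 0.0001, beta_end: 0.2}
optimizer: {name: adam, learning_rate: 0.002}
data: {kind: synthetic, n_records: 2000, fs: 64.0, duration_s: 2.0, n_leads: 2}
train: {steps: 2000, batch_size: 16, log_every: 100, checkpoint_every: 500}
seed: 0
output_dir: runs/desk
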
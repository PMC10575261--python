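# Full-scale settings: 12-lead records (8 generated), 10 s at 100 Hz,
# 4 x 256-channel model, T=200 linear schedule, Adam 2e-4. GPU-scale:
# not intended for CPU test runs.
model:
  n_residual_layers: 4
  residual_channels: 256
  skip_channels: 256
  diff_embed_dims: [128, 256, 256]
  label_dim: 12
  signal_channels: 8
  spade: {d_model: 256, window: 32, n_heads: 8, d_ffn: 512, ssm_state_dim: 64}
schedule: {T: 200, beta_start: 0.0001, beta_end: 0.02}
optimizer: {name: adam, learning_rate: 0.0002}
data: {kind: synthetic, n_records: 17441, fs: 100.0, duration_s: 10.0, n_leads: 8}
train: {steps: 100000, batch_size: 16, log_every: 100, checkpoint_every: 1000}
seed: 0
output_dir: runs/paper
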
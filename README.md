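# ecgdiff

Conditional denoising-diffusion synthesis of multi-lead ECG signals. The
denoiser is a stack of gated residual blocks (DiffWave lineage) whose sequence
mixer combines a structured state-space (S4) branch for global context with
sliding-window local attention, conditioned on a binary multilabel rhythm
vector and a sinusoidal diffusion-step embedding. The package also provides:

- reconstruction of the full 12-lead record from the 8 generated leads
  (I, aVF, V1–V6) via the Einthoven/Goldberger identities;
- quality metrics (dynamic time warping, RBF-kernel maximum mean discrepancy)
  and authenticity metrics (multilabel accuracy, macro AUROC under a
  classifier-transfer protocol) with a small 1-D residual classifier harness;
- a class-conditional synthetic ECG generator so everything is trainable and
  testable on one CPU with no downloads, plus a minimal WFDB reader/writer
  for real PhysioNet-style records.

Everything runs on NumPy: the network layers are built on a small
reverse-mode autodiff engine (`ecgdiff.nn`) with Adam, so no deep-learning
framework is required.

## Layout

| module | contents |
| --- | --- |
| `ecgdiff.nn` | autodiff engine, layers (conv1d, banded attention, layer norm), Adam |
| `ecgdiff.ssm` | HiPPO construction, bilinear discretization, recurrent + convolutional SSM paths |
| `ecgdiff.spade` | hybrid global (SSM) / local (windowed attention) layers |
| `ecgdiff.diffusion` | noise schedule, forward noising, eps-loss, ancestral sampler |
| `ecgdiff.model` | the conditional eps-prediction denoiser |
| `ecgdiff.leads` | 8-to-12-lead reconstruction |
| `ecgdiff.evaluation` | DTW, MMD, multilabel accuracy/AUROC, protocols, harness classifier |
| `ecgdiff.synth` | synthetic dataset generator, WFDB I/O, patient-grouped splits |
| `ecgdiff.cli`, `ecgdiff.config` | `ecgdiff` command line, YAML run configs, profiles |

## CLI

Two shipped profiles: `desk` (2-lead, L=128 synthetic data, 2×32-channel
model, T=100 — minutes on a CPU) and `paper` (8-lead 10 s @ 100 Hz records,
4×256-channel model, T=200 with β from 1e-4 to 0.02, Adam 2e-4 — GPU scale).

```bash
# train on the bundled synthetic data (desk profile)
ecgdiff train --profile desk --seed 0

# generate 64 records conditioned on class [1,0]
ecgdiff sample runs/desk/checkpoint.h5 --labels 1,0 -n 64 --seed 1 \
    --out generated.h5

# make a held-out real set and evaluate generated vs real
ecgdiff synth-data --n-records 256 --seed 9 --out real.h5
ecgdiff evaluate real.h5 generated.h5 --batch-size 16 --out report
```

`ecgdiff train --config my.yaml` accepts a YAML file validated against the
schema in `ecgdiff.config`; every run writes its resolved config next to its
outputs, and checkpoints are resumable (`--resume`). Training tracks an
exponential moving average of the weights (decay 0.995); checkpoints store
both, training resumes from the raw weights, and `sample` uses the EMA.

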
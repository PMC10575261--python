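"""Seeded training loop for the denoiser, with resumable checkpoints and
exponential-moving-average weights for sampling."""
from __future__ import annotations

import numpy as np

from . import nn
from .diffusion import DiffusionBatch, NoiseSchedule, training_loss
from .io import save_checkpoint
from .model import EpsPredictor

__all__ = ["train_model"]


def train_model(model: EpsPredictor, schedule: NoiseSchedule,
                records: np.ndarray, labels: np.ndarray, steps: int,
                lr: float = 2e-4, batch_size: int = 16, seed: int = 0,
                log_every: int = 50, checkpoint_path: str | None = None,
                checkpoint_every: int = 0,
                optimizer_state: dict | None = None,
                rng_state: dict | None = None, start_step: int = 0,
                ema_decay: float | None = 0.995,
                ema_state: dict | None = None,
                log=print) -> list[float]:
    """Adam training of the eps-predictor on (records, labels).

    Returns the per-step loss trace. Passing optimizer_state/rng_state/
    ema_state/start_step (from a checkpoint) resumes a previous run.

    When ema_decay is set (default), an exponential moving average of the
    parameters is tracked and written into the model IN PLACE once training
    finishes — the returned model carries the (better-sampling) averaged
    weights, while checkpoints keep the raw weights plus the EMA state so
    training can resume exactly.
    """
    opt = nn.Adam(model.parameters(), lr=lr)
    if optimizer_state is not None:
        opt.load_state_dict(optimizer_state)
    rng = np.random.default_rng(seed)
    if rng_state is not None:
        rng.bit_generator.state = rng_state
    params = model.parameters()
    ema = None
    if ema_decay is not None:
        if ema_state is not None:
            ema = {k: np.asarray(v).copy() for k, v in ema_state.items()}
        else:
            ema = {k: p.data.copy() for k, p in params.items()}
    extra = {"length": int(records.shape[-1])}
    n = len(records)
    losses: list[float] = []
    for step in range(start_step, start_step + steps):
        idx = rng.integers(0, n, size=batch_size)
        batch = DiffusionBatch(
            x0=records[idx],
            t=rng.integers(1, schedule.T + 1, size=batch_size),
            c=labels[idx],
            eps=rng.standard_normal(records[idx].shape),
        )
        loss = training_loss(model.forward, batch, schedule)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if ema is not None:
            for k, p in params.items():
                ema[k] += (1.0 - ema_decay) * (p.data - ema[k])
        losses.append(float(loss.data))
        if log and log_every and (step + 1) % log_every == 0:
            recent = np.mean(losses[-log_every:])
            log(f"step {step + 1}: loss {recent:.4f}")
        if (checkpoint_path and checkpoint_every
                and (step + 1) % checkpoint_every == 0):
            save_checkpoint(checkpoint_path, model, schedule, step + 1,
                            optimizer_state=opt.state_dict(),
                            rng_state=rng.bit_generator.state,
                            ema_state=ema, extra=extra)
    if checkpoint_path:
        save_checkpoint(checkpoint_path, model, schedule,
                        start_step + steps, optimizer_state=opt.state_dict(),
                        rng_state=rng.bit_generator.state,
                        ema_state=ema, extra=extra)
    if ema is not None:
        for k, p in params.items():
            p.data[...] = ema[k]
    return losses
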
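"""Denoising-diffusion machinery: linear noise schedule, forward noising,
the simplified eps-prediction loss, and ancestral reverse sampling.

Conventions: diffusion steps t are 1-based in every public signature
(t ∈ {1, ..., T}); arrays are stored 0-based internally. A single integer
seed drives counter-based random streams so that reverse sampling is
reproducible independent of batch size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["NoiseSchedule", "make_schedule", "forward_diffuse",
           "training_loss", "reverse_sample", "DiffusionBatch"]


@dataclass(frozen=True)
class NoiseSchedule:
    T: int
    beta: np.ndarray       # (T,)
    alpha: np.ndarray      # (T,)  alpha_t = 1 - beta_t
    alpha_bar: np.ndarray  # (T,)  cumulative product of alpha


def make_schedule(T: int, beta_start: float = 1e-4,
                  beta_end: float = 0.02) -> NoiseSchedule:
    """Linear schedule from beta_start to beta_end inclusive."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return NoiseSchedule(T=T, beta=beta, alpha=alpha,
                         alpha_bar=np.cumprod(alpha))


@dataclass
class DiffusionBatch:
    x0: np.ndarray     # (B, ...) clean signals
    t: np.ndarray      # (B,) integer steps in [1, T]
    c: np.ndarray      # (B, C) binary label vectors
    eps: np.ndarray    # same shape as x0, standard normal


def _check_t(t, T: int) -> np.ndarray:
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > T):
        raise IndexError(f"t must lie in [1, {T}], got range "
                         f"[{t.min()}, {t.max()}]")
    return t


def forward_diffuse(x0: np.ndarray, t, eps: np.ndarray,
                    schedule: NoiseSchedule,
                    sqrt_noise_weight: bool = True) -> np.ndarray:
    """x_t = √ᾱ_t·x0 + √(1−ᾱ_t)·eps  (element-wise; t may be per-record).

    sqrt_noise_weight=False reproduces the no-root noise weighting for audit;
    it does not give unit-variance marginals and is never the default.
    """
    x0, eps = np.asarray(x0, dtype=float), np.asarray(eps, dtype=float)
    if x0.shape != eps.shape:
        raise ValueError(f"x0 shape {x0.shape} != eps shape {eps.shape}")
    t = _check_t(t, schedule.T)
    ab = schedule.alpha_bar[t - 1]
    ab = ab.reshape(ab.shape + (1,) * (x0.ndim - ab.ndim))
    w = np.sqrt(1 - ab) if sqrt_noise_weight else (1 - ab)
    return np.sqrt(ab) * x0 + w * eps


def training_loss(predictor, batch: DiffusionBatch,
                  schedule: NoiseSchedule):
    """Mean squared error ‖eps − predictor(x_t, t, c)‖² averaged over all
    elements. Returns a Tensor when the predictor returns one (so gradients
    flow), else a float."""
    xt = forward_diffuse(batch.x0, batch.t, batch.eps, schedule)
    pred = predictor(xt, batch.t, batch.c)
    if isinstance(pred, Tensor):
        if pred.shape != batch.eps.shape:
            raise ValueError(
                f"prediction shape {pred.shape} != eps shape {batch.eps.shape}")
        diff = pred - Tensor(batch.eps)
        return (diff * diff).mean()
    pred = np.asarray(pred)
    if pred.shape != batch.eps.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != eps shape {batch.eps.shape}")
    return float(np.mean((batch.eps - pred) ** 2))


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def reverse_sample(predictor, c: np.ndarray, schedule: NoiseSchedule,
                   shape: tuple, seed: int, sigma: str = "beta") -> np.ndarray:
    """Ancestral sampling from t=T down to 1, starting at x_T ~ N(0, 1):

        x_{t−1} = (x_t − (1−α_t)/√(1−ᾱ_t)·eps_hat) / √α_t + σ_t·z

    with z ~ N(0,1) for t > 1 and z = 0 at the final step. sigma="beta" uses
    σ_t² = β_t; sigma="posterior" uses the posterior variance β̃_t.
    """
    if sigma not in ("beta", "posterior"):
        raise ValueError(f"unknown sigma mode {sigma!r}")
    T = schedule.T
    x = _stream(seed, 0).standard_normal(shape)
    n = shape[0] if len(shape) > 0 else 1
    for t in range(T, 0, -1):
        a = schedule.alpha[t - 1]
        ab = schedule.alpha_bar[t - 1]
        eps_hat = predictor(x, np.full(n, t, dtype=int), c)
        if isinstance(eps_hat, Tensor):
            eps_hat = eps_hat.data
        x = (x - (1 - a) / np.sqrt(1 - ab) * eps_hat) / np.sqrt(a)
        if not np.isfinite(x).all():
            raise FloatingPointError(
                f"non-finite sample values at reverse step t={t}")
        if t > 1:
            if sigma == "beta":
                var = schedule.beta[t - 1]
            else:
                ab_prev = schedule.alpha_bar[t - 2]
                var = (1 - ab_prev) / (1 - ab) * schedule.beta[t - 1]
            x = x + np.sqrt(var) * _stream(seed, t).standard_normal(shape)
    return x
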
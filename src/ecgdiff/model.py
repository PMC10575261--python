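"""The conditional eps-prediction denoiser: a stack of gated residual blocks
(DiffWave lineage) whose sequence mixer is a hybrid state-space/local-attention
stack, with a three-level diffusion-step embedding and multilabel conditioning
injected in every block and again after the skip-sum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .spade import SpadeConfig, SpadeLayer, SpadeStack

__all__ = ["ModelConfig", "EpsPredictor", "sinusoidal_embedding",
           "paper_config", "desk_config"]


@dataclass
class ModelConfig:
    n_residual_layers: int = 4
    residual_channels: int = 256
    skip_channels: int = 256
    diff_embed_dims: tuple[int, int, int] = (128, 256, 256)
    label_dim: int = 12
    signal_channels: int = 8
    spade: SpadeConfig = field(default_factory=lambda: SpadeConfig(d_model=256))

    def __post_init__(self):
        if len(self.diff_embed_dims) != 3:
            raise ValueError("diff_embed_dims must have exactly three entries")
        if min(self.n_residual_layers, self.residual_channels,
               self.skip_channels, self.label_dim, self.signal_channels,
               *self.diff_embed_dims) < 1:
            raise ValueError("all widths/counts must be >= 1")
        if self.spade.d_model != self.residual_channels:
            raise ValueError(
                f"spade.d_model ({self.spade.d_model}) must equal "
                f"residual_channels ({self.residual_channels})")


def paper_config(label_dim: int = 12, signal_channels: int = 8) -> ModelConfig:
    """Full-scale configuration (GPU-scale; not used by the test suite)."""
    return ModelConfig(
        n_residual_layers=4, residual_channels=256, skip_channels=256,
        diff_embed_dims=(128, 256, 256), label_dim=label_dim,
        signal_channels=signal_channels,
        spade=SpadeConfig(d_model=256, window=32, n_heads=8, d_ffn=512,
                          ssm_state_dim=64))


def desk_config(label_dim: int = 2, signal_channels: int = 2) -> ModelConfig:
    """CPU-trainable configuration used by the tests and the desk profile."""
    return ModelConfig(
        n_residual_layers=2, residual_channels=32, skip_channels=32,
        diff_embed_dims=(32, 64, 64), label_dim=label_dim,
        signal_channels=signal_channels,
        spade=SpadeConfig(d_model=32, window=8, n_heads=4, d_ffn=64,
                          ssm_state_dim=16))


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sin/cos position code of width `dim` for integer steps t (B,)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:  # odd dim: pad one zero column
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb


def _swish(x: Tensor) -> Tensor:
    return x * x.sigmoid()


class _ResidualBlock(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        C = cfg.residual_channels
        self.t_proj = nn.Linear(cfg.diff_embed_dims[2], C, rng)
        self.spade = SpadeStack(cfg.spade, rng)
        self.label_proj = nn.Linear(cfg.label_dim, C, rng)
        self.mid = nn.Conv1d(C, 2 * C, 1, rng)
        self.res_out = nn.Conv1d(C, C, 1, rng)
        self.skip_out = nn.Conv1d(C, cfg.skip_channels, 1, rng)
        self._C = C

    def forward(self, x: Tensor, t_emb: Tensor, c: Tensor):
        B, C, L = x.shape
        h = x + self.t_proj(t_emb).reshape(B, C, 1)
        h = self.spade(h.transpose(0, 2, 1)).transpose(0, 2, 1)
        h = h + self.label_proj(c).reshape(B, C, 1)
        g = self.mid(h)
        gated = g[:, :self._C, :].tanh() * g[:, self._C:, :].sigmoid()
        res = (x + self.res_out(gated)) * (1.0 / math.sqrt(2.0))
        return res, self.skip_out(gated)


class EpsPredictor(nn.Module):
    """Maps (x_t, t, c) to the predicted noise, same shape as x_t."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d0, d1, d2 = cfg.diff_embed_dims
        self.embed_fc1 = nn.Linear(d0, d1, rng)
        self.embed_fc2 = nn.Linear(d1, d2, rng)
        self.input_proj = nn.Conv1d(cfg.signal_channels,
                                    cfg.residual_channels, 1, rng)
        self.blocks = [_ResidualBlock(cfg, rng)
                       for _ in range(cfg.n_residual_layers)]
        # post-skip-sum global layer, conditioned a second time
        self.post_label_proj = nn.Linear(cfg.label_dim, cfg.skip_channels, rng)
        post_cfg = SpadeConfig(
            d_model=cfg.skip_channels, window=cfg.spade.window,
            n_heads=math.gcd(cfg.spade.n_heads, cfg.skip_channels),
            d_ffn=cfg.spade.d_ffn, ssm_state_dim=cfg.spade.ssm_state_dim)
        self.post_spade = SpadeLayer(post_cfg, rng, use_ssm=True)
        self.out_conv1 = nn.Conv1d(cfg.skip_channels, cfg.skip_channels, 1, rng)
        self.out_conv2 = nn.Conv1d(cfg.skip_channels,
                                   cfg.signal_channels, 1, rng)

    def diffusion_embedding(self, t: np.ndarray) -> Tensor:
        """Three-level embedding: sinusoidal code then two swish MLP stages."""
        t = np.atleast_1d(t)
        if np.any(t < 1):
            raise ValueError("diffusion steps are 1-based; got t < 1")
        e = Tensor(sinusoidal_embedding(t, self.cfg.diff_embed_dims[0]))
        return _swish(self.embed_fc2(_swish(self.embed_fc1(e))))

    def forward(self, xt, t, c) -> Tensor:
        xt = xt if isinstance(xt, Tensor) else Tensor(xt)
        c = c if isinstance(c, Tensor) else Tensor(c)
        B, ch, L = xt.shape
        if ch != self.cfg.signal_channels:
            raise ValueError(
                f"input has {ch} channels, model expects "
                f"{self.cfg.signal_channels}")
        if c.shape != (B, self.cfg.label_dim):
            raise ValueError(
                f"label batch shape {c.shape} != {(B, self.cfg.label_dim)}")
        t_emb = self.diffusion_embedding(t)
        h = self.input_proj(xt).relu()
        skip_total = None
        for block in self.blocks:
            h, skip = block(h, t_emb, c)
            skip_total = skip if skip_total is None else skip_total + skip
        s = skip_total * (1.0 / math.sqrt(len(self.blocks)))
        s = s + self.post_label_proj(c).reshape(B, self.cfg.skip_channels, 1)
        s = self.post_spade(s.transpose(0, 2, 1)).transpose(0, 2, 1)
        return self.out_conv2(self.out_conv1(s).relu())

    def predict(self, xt: np.ndarray, t, c: np.ndarray) -> np.ndarray:
        """Inference path: no autodiff graph, returns a NumPy array."""
        with nn.no_grad():
            return self.forward(xt, t, c).numpy()

    def parameter_groups(self) -> dict[str, list[str]]:
        """Named groups for gradient-coverage auditing."""
        groups: dict[str, list[str]] = {}
        for name in self.parameters():
            top = name.split(".")[0]
            groups.setdefault(top, []).append(name)
        return groups
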
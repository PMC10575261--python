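"""Hybrid global/local sequence layers: a state-space (S4) branch for global
context combined with sliding-window local attention.

Layer composition, with LN = layer normalization and W a learned projection
of the concatenated branch outputs back to d_model:

    X_local  = Local(LN(X))
    X_global = SSM(LN(X))
    X_a      = W [LN(X_local), LN(X_global)] + X
    Y        = FFN(LN(X_a)) + X_a

Local-only layers (the non-global levels of the hierarchy) drop the SSM
branch: X_a = W·LN(X_local) + X.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .ssm import hippo_matrix

__all__ = ["SpadeConfig", "LocalAttention", "S4Branch", "SpadeLayer",
           "SpadeStack", "local_attention_mask"]


@dataclass
class SpadeConfig:
    d_model: int
    window: int = 16          # positions attended on each side of self
    n_heads: int = 4
    d_ffn: int = 64
    ssm_state_dim: int = 16
    n_local_layers: int = 1   # local-only layers stacked above the global one

    def __post_init__(self):
        if min(self.d_model, self.n_heads, self.d_ffn, self.ssm_state_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")


def local_attention_mask(L: int, window: int) -> np.ndarray:
    """(L, L) additive mask: 0 where |i−j| <= window, −inf elsewhere."""
    i = np.arange(L)
    mask = np.where(np.abs(i[:, None] - i[None, :]) <= window, 0.0, -np.inf)
    return mask


class LocalAttention(nn.Module):
    """Multi-head scaled-dot-product attention restricted to a symmetric
    sliding window; position i attends to j with |i−j| <= window."""

    def __init__(self, cfg: SpadeConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.cfg = cfg
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self._masks: dict[int, np.ndarray] = {}

    def _heads(self, t: Tensor, B: int, L: int) -> Tensor:
        H = self.cfg.n_heads
        return t.reshape(B, L, H, self.cfg.d_model // H).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite attention input")
        q = self._heads(self.wq(x), B, L)
        k = self._heads(self.wk(x), B, L)
        v = self._heads(self.wv(x), B, L)
        out = nn.banded_attention(q, k, v, self.cfg.window)
        return self.wo(out.transpose(0, 2, 1, 3).reshape(B, L, d))

    def forward_dense(self, x: Tensor) -> Tensor:
        """Dense masked-softmax path; reference for the banded kernel."""
        B, L, d = x.shape
        dh = d // self.cfg.n_heads
        mask = self._masks.get(L)
        if mask is None:
            mask = self._masks[L] = local_attention_mask(L, self.cfg.window)
        q = self._heads(self.wq(x), B, L)
        k = self._heads(self.wk(x), B, L)
        v = self._heads(self.wv(x), B, L)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(dh))
        attn = nn.softmax(scores, axis=-1, mask=mask)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(out)


class S4Branch(nn.Module):
    """One independent S4 per feature channel (diagonal over channels).

    A and B use the stable LegS construction; the per-channel step size δ is a
    fixed buffer drawn log-uniform in [1e−3, 1e−1]; C (per-channel output map)
    and the feedthrough D are learnable. The length-L kernels are K = C·S
    with S[c, :, l] = Ā_c^l·B̄_c precomputed once per (δ, L).
    """

    def __init__(self, d_model: int, state_dim: int, rng: np.random.Generator):
        self.d = d_model
        self.N = state_dim
        A, B = hippo_matrix(state_dim, form="legs")
        self._A, self._B = A, B
        self.log_delta = np.log(10.0 ** rng.uniform(-3, -1, size=d_model))
        self.C = nn.Parameter(rng.standard_normal((d_model, state_dim))
                              / np.sqrt(state_dim))
        self.D = nn.Parameter(np.ones(d_model))
        self._state_cache: dict[int, np.ndarray] = {}

    def _states(self, L: int) -> np.ndarray:
        """(d, N, L) array of Ā_c^l·B̄_c for each channel c."""
        S = self._state_cache.get(L)
        if S is not None:
            return S
        I = np.eye(self.N)
        S = np.empty((self.d, self.N, L))
        for c in range(self.d):
            delta = np.exp(self.log_delta[c])
            Minv = np.linalg.inv(I - delta / 2 * self._A)
            A_bar = Minv @ (I + delta / 2 * self._A)
            x = Minv @ (delta * self._B)
            for l in range(L):
                S[c, :, l] = x
                x = A_bar @ x
        self._state_cache[L] = S
        return S

    def forward(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        S = Tensor(self._states(L))                    # constant buffer
        K = (self.C.reshape(d, self.N, 1) * S).sum(axis=1)   # (d, L)
        u = x.transpose(0, 2, 1)                       # (B, d, L)
        y = nn.causal_conv(u, K) + self.D.reshape(1, d, 1) * u
        return y.transpose(0, 2, 1)


class SpadeLayer(nn.Module):
    """Global layer (SSM branch + local attention) or, with
    use_ssm=False, a plain local layer with the same skeleton."""

    def __init__(self, cfg: SpadeConfig, rng: np.random.Generator,
                 use_ssm: bool = True):
        d = cfg.d_model
        self.cfg = cfg
        self.use_ssm = use_ssm
        self.ln_in = nn.LayerNorm(d)
        self.local = LocalAttention(cfg, rng)
        self.ln_local = nn.LayerNorm(d)
        if use_ssm:
            self.ssm = S4Branch(d, cfg.ssm_state_dim, rng)
            self.ln_global = nn.LayerNorm(d)
            self.w = nn.Linear(2 * d, d, rng)
        else:
            self.w = nn.Linear(d, d, rng)
        self.ln_ffn = nn.LayerNorm(d)
        self.ffn_in = nn.Linear(d, cfg.d_ffn, rng)
        self.ffn_out = nn.Linear(cfg.d_ffn, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        xn = self.ln_in(x)
        x_local = self.local(xn)
        if self.use_ssm:
            x_global = self.ssm(xn)
            if x_global.shape != x_local.shape:
                raise RuntimeError(
                    f"branch shape mismatch: local {x_local.shape}, "
                    f"global {x_global.shape}")
            merged = nn.concat([self.ln_local(x_local),
                                self.ln_global(x_global)], axis=-1)
        else:
            merged = self.ln_local(x_local)
        xa = self.w(merged) + x
        return self.ffn_out(self.ffn_in(self.ln_ffn(xa)).gelu()) + xa


class SpadeStack(nn.Module):
    """One global layer followed by cfg.n_local_layers local-only layers."""

    def __init__(self, cfg: SpadeConfig, rng: np.random.Generator):
        self.layers = [SpadeLayer(cfg, rng, use_ssm=True)]
        self.layers += [SpadeLayer(cfg, rng, use_ssm=False)
                        for _ in range(cfg.n_local_layers)]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
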
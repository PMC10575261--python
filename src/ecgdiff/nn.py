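"""Minimal reverse-mode autodiff on NumPy arrays, with the layers and the
optimizer used by the denoiser network and the evaluation classifier.

Everything is float64 and single-threaded-deterministic. The engine supports
exactly the operations the package needs; it is not a general framework.
"""
from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable

import numpy as np
from scipy import special

__all__ = [
    "Tensor", "no_grad", "tensor", "concat", "softmax", "layer_norm",
    "conv1d", "causal_conv", "Module", "Parameter", "Linear", "Conv1d",
    "LayerNorm", "Adam", "numeric_grad",
]

_GRAD_ENABLED = True
DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """float64 (default, used by the oracle tests) or float32 (fast training)."""
    global DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    DEFAULT_DTYPE = np.dtype(dtype).type


@contextmanager
def default_dtype(dtype):
    global DEFAULT_DTYPE
    prev = DEFAULT_DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        DEFAULT_DTYPE = prev


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = _parents if _GRAD_ENABLED else ()
        self._backward = _backward if _GRAD_ENABLED else None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- ops -----------------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            self._accum(-g)
        out._backward = bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = tensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires both operands to be >= 2-D")
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * y)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            self._accum(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * (1 - y * y))
        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        y = special.expit(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * y * (1 - y))
        out._backward = bw if out.requires_grad else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bw(g):
            self._accum(g * (self.data > 0))
        out._backward = bw if out.requires_grad else None
        return out

    def gelu(self):
        """Exact GELU: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1 + special.erf(x / math.sqrt(2)))
        out = Tensor(x * phi, self.requires_grad, (self,))

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
            self._accum(g * (phi + x * pdf))
        out._backward = bw if out.requires_grad else None
        return out

    def softplus(self):
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * special.expit(self.data))
        out._backward = bw if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def bw(g):
            self._accum(np.swapaxes(g, a, b))
        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw if out.requires_grad else None
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Fused softmax; `mask` is an additive constant (may contain −inf)."""
    x = tensor(x)
    z = x.data if mask is None else x.data + mask
    z = z - z.max(axis=axis, keepdims=True)
    y = np.exp(z)
    y /= y.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        gy = g * y
        x._accum(gy - y * gy.sum(axis=axis, keepdims=True))
    out._backward = bw if out.requires_grad else None
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    x, gamma, beta = tensor(x), tensor(gamma), tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            x._accum(inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)))
    out._backward = bw if out.requires_grad else None
    return out


def banded_attention(q: Tensor, k: Tensor, v: Tensor, window: int) -> Tensor:
    """Fused sliding-window attention: position i attends to |i−j| <= window.

    q, k, v: (B, H, L, dh). Equivalent to dense softmax(q·kᵀ/√dh + band mask)·v
    but computed on the (2·window+1)-wide band only.
    """
    q, k, v = tensor(q), tensor(k), tensor(v)
    B, H, L, dh = q.data.shape
    w = int(window)
    W = 2 * w + 1
    scale = 1.0 / math.sqrt(dh)
    pad = ((0, 0), (0, 0), (w, w), (0, 0))
    kwin = np.lib.stride_tricks.sliding_window_view(
        np.pad(k.data, pad), W, axis=2)          # (B,H,L,dh,W)
    vwin = np.lib.stride_tricks.sliding_window_view(
        np.pad(v.data, pad), W, axis=2)
    # offset o maps to key index j = i - w + o; mask out-of-range edges
    i = np.arange(L)[:, None]
    o = np.arange(W)[None, :]
    band_mask = np.where((i - w + o >= 0) & (i - w + o < L), 0.0, -np.inf)
    scores = np.einsum("bhld,bhldw->bhlw", q.data, kwin,
                       optimize=True) * scale + band_mask
    scores -= scores.max(axis=-1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=-1, keepdims=True)
    out_data = np.einsum("bhlw,bhldw->bhld", attn, vwin, optimize=True)
    out = Tensor(out_data,
                 q.requires_grad or k.requires_grad or v.requires_grad,
                 (q, k, v))

    def band_transpose(z: np.ndarray) -> np.ndarray:
        """zT[..., j, o] = z[..., j+o−w, 2w−o] (zero outside), as a view."""
        zp = np.pad(z[..., ::-1], ((0, 0), (0, 0), (w, w), (0, 0)))
        s = zp.strides
        return np.lib.stride_tricks.as_strided(
            zp, shape=(B, H, L, W), strides=s[:3] + (s[2] + s[3],))

    def bw(g):
        gattn = np.einsum("bhld,bhldw->bhlw", g, vwin, optimize=True)
        gwin = np.lib.stride_tricks.sliding_window_view(
            np.pad(g, pad), W, axis=2)           # (B,H,L,dh,W)
        if v.requires_grad:
            v._accum(np.einsum("bhjo,bhjdo->bhjd", band_transpose(attn),
                               gwin, optimize=True))
        gs = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        if q.requires_grad:
            q._accum(np.einsum("bhlw,bhldw->bhld", gs, kwin,
                               optimize=True) * scale)
        if k.requires_grad:
            qwin = np.lib.stride_tricks.sliding_window_view(
                np.pad(q.data, pad), W, axis=2)
            k._accum(np.einsum("bhjo,bhjdo->bhjd", band_transpose(gs),
                               qwin, optimize=True) * scale)
    out._backward = bw if out.requires_grad else None
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 1-D convolution (cross-correlation convention).

    x: (B, C_in, L); w: (C_out, C_in, k) with odd k; b: (C_out,).
    """
    x, w = tensor(x), tensor(w)
    B, Ci, L = x.data.shape
    Co, Ci2, k = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, weight {Ci2}")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)  # B,Ci,L,k
    y = np.einsum("bilk,oik->bol", win, w.data, optimize=True)
    parents = (x, w) if b is None else (x, w, tensor(b))
    if b is not None:
        bt = parents[2]
        y = y + bt.data[:, None]
    out = Tensor(y, any(t.requires_grad for t in parents), parents)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bol,bilk->oik", g, win, optimize=True))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (k - 1 - p, k - 1 - p)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=-1)
            x._accum(np.einsum("bolk,oik->bil", gwin, w.data[:, :, ::-1],
                               optimize=True))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(g.sum(axis=(0, 2)))
    out._backward = bw if out.requires_grad else None
    return out


def causal_conv(u: Tensor, K: Tensor) -> Tensor:
    """Per-channel causal convolution: y[b,c,l] = sum_{j<=l} K[c,j] u[b,c,l-j].

    u: (B, C, L); K: (C, L). FFT-based, O(L log L) per channel.
    """
    u, K = tensor(u), tensor(K)
    B, C, L = u.data.shape
    if K.data.shape != (C, L):
        raise ValueError(f"kernel shape {K.data.shape} != {(C, L)}")
    n = 2 * L
    Uf = np.fft.rfft(u.data, n=n)
    Kf = np.fft.rfft(K.data, n=n)
    y = np.fft.irfft(Uf * Kf, n=n)[..., :L]
    out = Tensor(y, u.requires_grad or K.requires_grad, (u, K))

    def bw(g):
        Gf = np.fft.rfft(g, n=n)
        if u.requires_grad:
            u._accum(np.fft.irfft(Gf * np.conj(Kf), n=n)[..., :L])
        if K.requires_grad:
            K._accum(np.fft.irfft(Gf * np.conj(Uf), n=n)[..., :L].sum(axis=0))
    out._backward = bw if out.requires_grad else None
    return out


# --------------------------------------------------------------------------
# Modules


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Tiny module system: parameters are discovered by attribute walk."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, t in val.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{name}.{i}"] = item
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable array state (public ndarray attributes), for
        checkpointing; traversal mirrors parameters()."""
        out: dict[str, np.ndarray] = {}
        for name, val in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(val, np.ndarray):
                out[name] = val
            elif isinstance(val, Module):
                for sub, a in val.buffers().items():
                    out[f"{name}.{sub}"] = a
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, a in item.buffers().items():
                            out[f"{name}.{i}.{sub}"] = a
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / math.sqrt(d_in)
        self.w = Parameter(rng.standard_normal((d_in, d_out)) * scale)
        self.b = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded 1-D convolution layer; kernel_size=1 is a channel mix."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / math.sqrt(c_in * kernel_size)
        self.w = Parameter(rng.standard_normal((c_out, c_in, kernel_size)) * scale)
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 2e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": dict(self.m), "v": dict(self.v)}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}


def numeric_grad(f: Callable[[], Tensor], param: Tensor,
                 eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f with respect to param (test aid)."""
    g = np.zeros_like(param.data)
    flat = param.data.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(f().data)
        flat[i] = orig - eps
        lo = float(f().data)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
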
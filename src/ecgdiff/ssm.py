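"""Structured state-space models: HiPPO construction, bilinear discretization,
and the recurrent (oracle) and convolutional (production) application paths.

The recurrent path steps the state update directly and is the exactness
reference; the convolutional path materializes the length-L kernel
K[k] = C·Ā^k·B̄ and applies it as a causal convolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SSMParams", "DiscreteSSM", "build_hippo", "hippo_matrix", "discretize",
    "ssm_apply_recurrent", "ssm_apply_conv",
]


@dataclass
class SSMParams:
    """Continuous-time single-input single-output state-space system."""

    A: np.ndarray          # (N, N) state matrix
    B: np.ndarray          # (N,) input map
    C: np.ndarray          # (N,) output map
    delta: float           # step size > 0
    D: float = 0.0         # optional feedthrough scalar

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.B.ndim != 1 or self.B.shape[0] < 1:
            raise ValueError(f"B must be a non-empty vector, got shape {self.B.shape}")
        N = self.N
        if self.A.shape != (N, N):
            raise ValueError(f"A must be square NxN, got {self.A.shape}")
        if self.C.shape != (N,):
            raise ValueError(f"C must have shape ({N},), got {self.C.shape}")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        for name in ("A", "B", "C"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite entries in {name}")

    @property
    def N(self) -> int:
        return self.B.shape[0]


@dataclass
class DiscreteSSM:
    """Discretized system with its length-L convolution kernel."""

    A_bar: np.ndarray      # (N, N)
    B_bar: np.ndarray      # (N,)
    C_bar: np.ndarray      # (N,)
    L: int
    D: float = 0.0
    _kernel: np.ndarray | None = field(default=None, repr=False)

    @property
    def K_bar(self) -> np.ndarray:
        """Kernel (C̄B̄, C̄ĀB̄, ..., C̄Ā^{L-1}B̄), materialized lazily."""
        if self._kernel is None:
            K = np.empty(self.L)
            x = self.B_bar.copy()
            for k in range(self.L):
                K[k] = self.C_bar @ x
                x = self.A_bar @ x
            self._kernel = K
        return self._kernel


def hippo_matrix(N: int, form: str = "printed") -> tuple[np.ndarray, np.ndarray]:
    """Return (A, B) for state dimension N.

    form="printed": off-diagonal entries of A^(ds) are -((i+1/2)(j+1/2))^(1/2)
    on BOTH sides of the +1/2 diagonal. form="legs": sign flipped above the
    diagonal and -1/2 on it, which makes A - P·Pᵀ the (stable) LegS matrix.
    """
    if N < 1:
        raise ValueError(f"state dimension must be >= 1, got {N}")
    idx = np.arange(N, dtype=float)
    P = np.sqrt(idx + 0.5)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    off = np.sqrt((ii + 0.5) * (jj + 0.5))
    if form == "printed":
        Ads = -off
        np.fill_diagonal(Ads, 0.5)
    elif form == "legs":
        Ads = np.where(ii < jj, off, -off)
        np.fill_diagonal(Ads, -0.5)
    else:
        raise ValueError(f"unknown form {form!r}; use 'printed' or 'legs'")
    A = Ads - np.outer(P, P)
    B = np.sqrt(2 * idx + 1.0)
    return A, B


def build_hippo(N: int, delta: float = 0.01, seed: int = 0,
                form: str = "printed") -> SSMParams:
    """HiPPO-initialized system: A = A^(ds) − P·Pᵀ, B_i = (2i+1)^(1/2),
    C drawn from a seeded standard normal, D = 0."""
    A, B = hippo_matrix(N, form=form)
    C = np.random.default_rng(seed).standard_normal(N)
    return SSMParams(A=A, B=B, C=C, delta=delta)


def discretize(params: SSMParams, L: int) -> DiscreteSSM:
    """Bilinear transform: Ā = (I − δ/2·A)⁻¹(I + δ/2·A), B̄ = (I − δ/2·A)⁻¹δB."""
    if L < 1:
        raise ValueError(f"kernel length must be >= 1, got {L}")
    N = params.N
    I = np.eye(N)
    M = I - params.delta / 2 * params.A
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"(I - delta/2*A) is singular for delta={params.delta}") from e
    A_bar = Minv @ (I + params.delta / 2 * params.A)
    B_bar = Minv @ (params.delta * params.B)
    return DiscreteSSM(A_bar=A_bar, B_bar=B_bar, C_bar=params.C.copy(),
                       L=L, D=params.D)


def _check_input(ssm: DiscreteSSM, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (ssm.L,):
        raise ValueError(f"input length {u.shape} != kernel length ({ssm.L},)")
    if not np.isfinite(u).all():
        raise ValueError("non-finite input")
    return u


def ssm_apply_recurrent(ssm: DiscreteSSM, u: np.ndarray) -> np.ndarray:
    """Step x_k = Ā x_{k−1} + B̄ u_k, y_k = C̄ x_k (+ D u_k), x_{−1} = 0."""
    u = _check_input(ssm, u)
    y = np.empty(ssm.L)
    x = np.zeros(ssm.A_bar.shape[0])
    for k in range(ssm.L):
        x = ssm.A_bar @ x + ssm.B_bar * u[k]
        y[k] = ssm.C_bar @ x + ssm.D * u[k]
    return y


def ssm_apply_conv(ssm: DiscreteSSM, u: np.ndarray) -> np.ndarray:
    """Causal convolution y = K̄ ∗ u truncated to length L (+ D u)."""
    u = _check_input(ssm, u)
    n = 2 * ssm.L
    y = np.fft.irfft(np.fft.rfft(u, n=n) * np.fft.rfft(ssm.K_bar, n=n), n=n)
    return y[:ssm.L] + ssm.D * u
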
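"""Generated-vs-real evaluation: DTW and RBF-kernel MMD for sample quality,
multilabel accuracy / macro AUROC under a classifier-transfer protocol for
authenticity, plus a small 1-D residual multilabel classifier harness.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from . import nn
from .nn import Tensor

__all__ = [
    "EvalReport", "dtw_distance", "mmd_rbf", "median_heuristic_sigma",
    "multilabel_accuracy", "multilabel_auroc", "quality_protocol",
    "authenticity_protocol", "ResidualClassifier1D", "train_classifier",
]


@dataclass
class EvalReport:
    avg_dtw: float = float("nan")
    mmd: float = float("nan")
    mmd_sigma: float = float("nan")
    multilabel_accuracy: float = float("nan")
    multilabel_auroc: float = float("nan")
    accuracy_real: float = float("nan")
    accuracy_generated: float = float("nan")
    auroc_real: float = float("nan")
    auroc_generated: float = float("nan")
    accuracy_gap: float = float("nan")
    auroc_gap: float = float("nan")
    n_real: int = 0
    n_generated: int = 0
    batch_size: int = 16

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.to_dict().items()) + "\n"


# --------------------------------------------------------------------------
# Quality metrics


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping distance with squared-difference local cost.

    D[i,j] = (x_i − y_j)² + min(D[i,j−1], D[i−1,j], D[i−1,j−1]),
    D[0,0] = 0 and +inf on the remaining borders; returns D[N,M].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("DTW inputs must be finite")
    M = y.size
    prev = np.full(M + 1, np.inf)
    prev[0] = 0.0
    for xi in x:
        cur = np.empty(M + 1)
        cur[0] = np.inf
        cost = (xi - y) ** 2
        for j in range(1, M + 1):
            cur[j] = cost[j - 1] + min(cur[j - 1], prev[j], prev[j - 1])
        prev = cur
    return float(prev[M])


def median_heuristic_sigma(X: np.ndarray, Y: np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled sample."""
    Z = np.vstack([X.reshape(len(X), -1), Y.reshape(len(Y), -1)])
    d = cdist(Z, Z)
    med = float(np.median(d[np.triu_indices(len(Z), k=1)]))
    return med if med > 0 else 1.0


def mmd_rbf(X: np.ndarray, Y: np.ndarray, sigma: float) -> float:
    """Unbiased-within-set MMD estimator with the RBF kernel
    k(x,y) = exp(−‖x−y‖² / (2σ²)):

        1/(n(n−1)) Σ_{i≠j} k(x_i,x_j) + 1/(m(m−1)) Σ_{i≠j} k(y_i,y_j)
        − 2/(nm) Σ_i Σ_j k(x_i,y_j)
    """
    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    Y = np.asarray(Y, dtype=float).reshape(len(Y), -1)
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError(f"need n,m >= 2 for the unbiased terms, got {n}, {m}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    g = 1.0 / (2 * sigma * sigma)
    kxx = np.exp(-g * cdist(X, X, "sqeuclidean"))
    kyy = np.exp(-g * cdist(Y, Y, "sqeuclidean"))
    kxy = np.exp(-g * cdist(X, Y, "sqeuclidean"))
    term_x = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    term_y = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    return float(term_x + term_y - 2.0 * kxy.mean())


# --------------------------------------------------------------------------
# Authenticity metrics


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def multilabel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of label positions predicted correctly, over all n·C slots."""
    pred, truth = _check_pair(pred, truth)
    return float((pred == truth).mean())


def multilabel_auroc(scores: np.ndarray, truth: np.ndarray,
                     return_skipped: bool = False):
    """Macro-averaged per-label AUROC; degenerate columns (single class) are
    skipped and optionally reported."""
    scores, truth = _check_pair(scores, truth)
    aurocs, skipped = [], []
    for j in range(truth.shape[1]):
        col = truth[:, j]
        if col.min() == col.max():
            skipped.append(j)
            continue
        aurocs.append(roc_auc_score(col, scores[:, j]))
    if not aurocs:
        raise ValueError("all label columns are degenerate; AUROC undefined")
    macro = float(np.mean(aurocs))
    return (macro, skipped) if return_skipped else macro


# --------------------------------------------------------------------------
# Protocols


def quality_protocol(real: np.ndarray, generated: np.ndarray,
                     batch_size: int = 16, sigma: float | None = None,
                     dtw_mode: str = "per_lead",
                     labels_real: np.ndarray | None = None,
                     labels_generated: np.ndarray | None = None) -> EvalReport:
    """Average pairwise DTW between index-paired records (within label-matched
    groups when labels are provided) and MMD over flattened records.

    The DTW work is processed in chunks of `batch_size`; chunking does not
    change the result, and MMD always uses the full sets.
    """
    real, generated = np.asarray(real, float), np.asarray(generated, float)
    if real.size == 0 or generated.size == 0:
        raise ValueError("empty record set")
    if real.shape[1:] != generated.shape[1:]:
        raise ValueError(
            f"record shape mismatch: {real.shape[1:]} vs {generated.shape[1:]}")
    if dtw_mode not in ("per_lead", "concat"):
        raise ValueError(f"unknown dtw_mode {dtw_mode!r}")

    if labels_real is not None and labels_generated is not None:
        pairs = _label_matched_pairs(labels_real, labels_generated)
    else:
        n = min(len(real), len(generated))
        pairs = list(zip(range(n), range(n)))

    dtws = []
    for start in range(0, len(pairs), batch_size):
        for i, j in pairs[start:start + batch_size]:
            a, b = real[i], generated[j]
            if dtw_mode == "concat":
                dtws.append(dtw_distance(a.ravel(), b.ravel()))
            else:
                dtws.append(np.mean([dtw_distance(a[ch], b[ch])
                                     for ch in range(a.shape[0])]))
    if sigma is None:
        sigma = median_heuristic_sigma(real, generated)
    return EvalReport(avg_dtw=float(np.mean(dtws)),
                      mmd=mmd_rbf(real, generated, sigma), mmd_sigma=sigma,
                      n_real=len(real), n_generated=len(generated),
                      batch_size=batch_size)


def _label_matched_pairs(labels_a: np.ndarray, labels_b: np.ndarray) -> list:
    """Index pairs matched within identical label vectors, by order."""
    keys_a = [tuple(row) for row in np.asarray(labels_a)]
    keys_b = [tuple(row) for row in np.asarray(labels_b)]
    by_key: dict[tuple, list[int]] = {}
    for j, k in enumerate(keys_b):
        by_key.setdefault(k, []).append(j)
    used: dict[tuple, int] = {}
    pairs = []
    for i, k in enumerate(keys_a):
        pos = used.get(k, 0)
        if k in by_key and pos < len(by_key[k]):
            pairs.append((i, by_key[k][pos]))
            used[k] = pos + 1
    return pairs


def authenticity_protocol(classifier, real_test, generated_test,
                          threshold: float = 0.5,
                          batch_size: int = 16) -> EvalReport:
    """Compare a real-data-trained classifier's accuracy/AUROC on real vs
    generated test sets; smaller gaps mean more authentic samples."""
    xr, yr = real_test
    xg, yg = generated_test
    yr, yg = np.asarray(yr, float), np.asarray(yg, float)
    if yr.shape[1] != yg.shape[1]:
        raise ValueError(
            f"label-space mismatch: {yr.shape[1]} vs {yg.shape[1]} labels")
    sr = classifier.predict_scores(np.asarray(xr, float))
    sg = classifier.predict_scores(np.asarray(xg, float))
    acc_r = multilabel_accuracy((sr >= threshold).astype(float), yr)
    acc_g = multilabel_accuracy((sg >= threshold).astype(float), yg)
    auc_r = multilabel_auroc(sr, yr)
    auc_g = multilabel_auroc(sg, yg)
    return EvalReport(
        accuracy_real=acc_r, accuracy_generated=acc_g,
        auroc_real=auc_r, auroc_generated=auc_g,
        accuracy_gap=abs(acc_r - acc_g), auroc_gap=abs(auc_r - auc_g),
        multilabel_accuracy=acc_g, multilabel_auroc=auc_g,
        n_real=len(yr), n_generated=len(yg), batch_size=batch_size)


# --------------------------------------------------------------------------
# Harness classifier


class ResidualClassifier1D(nn.Module):
    """Small 1-D residual convolutional multilabel classifier with sigmoid
    outputs; a desk-scale stand-in for a full ResNet-1D."""

    def __init__(self, in_channels: int, n_labels: int, width: int = 16,
                 depth: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = nn.Conv1d(in_channels, width, 7, rng)
        self.blocks = [
            (nn.Conv1d(width, width, 5, rng), nn.Conv1d(width, width, 5, rng))
            for _ in range(depth)
        ]
        self.head = nn.Linear(width, n_labels, rng)

    def parameters(self):
        out = {"stem." + k: v for k, v in self.stem.parameters().items()}
        for i, (c1, c2) in enumerate(self.blocks):
            out.update({f"block{i}.a.{k}": v
                        for k, v in c1.parameters().items()})
            out.update({f"block{i}.b.{k}": v
                        for k, v in c2.parameters().items()})
        out.update({"head." + k: v for k, v in self.head.parameters().items()})
        return out

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, C, L) -> logits (B, n_labels)."""
        h = self.stem(x).relu()
        for c1, c2 in self.blocks:
            h = (c2(c1(h).relu()) + h).relu()
            B, C, L = h.shape
            if L % 2 == 0:  # halve time resolution
                h = h.reshape(B, C, L // 2, 2).mean(axis=-1)
        h = h.mean(axis=-1)  # global average pool -> (B, C)
        return self.head(h)

    def predict_scores(self, records: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.forward(Tensor(records)).sigmoid().numpy()


def train_classifier(clf: ResidualClassifier1D, records: np.ndarray,
                     labels: np.ndarray, steps: int = 300, lr: float = 1e-2,
                     batch_size: int = 32, seed: int = 0) -> list[float]:
    """Binary-cross-entropy training; returns the per-step loss trace."""
    rng = np.random.default_rng(seed)
    opt = nn.Adam(clf.parameters(), lr=lr)
    losses = []
    for _ in range(steps):
        idx = rng.integers(0, len(records), size=batch_size)
        x = Tensor(records[idx])
        y = Tensor(labels[idx])
        z = clf(x)
        loss = (z.softplus() - z * y).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return losses
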
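"""Louvain community detection for signed weighted networks.

Maximizes a signed modularity in which positive weights follow the usual
Newman null model while negative weights enter with the asymmetric scheme:

    Q* = Q+ - s- / (s+ + s-) * Q-

where Q+/Q- are the modularity contributions of the positive/negative parts
of the weight matrix and s+/s- their total weight.  With no negative
weights this reduces to standard Newman-Girvan modularity.  The greedy
node-move phase plus community aggregation is iterated until no move
improves Q; node order is shuffled by the supplied RNG, so results are
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

_EPS = 1e-12


def signed_modularity_matrix(
    weights: np.ndarray, gamma: float = 1.0, scheme: str = "negative_asym"
) -> np.ndarray:
    """Generalized modularity matrix B such that Q = sum of B within
    communities."""
    W = np.asarray(weights, dtype=float).copy()
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InputError("weight matrix must be square")
    if not np.isfinite(W).all():
        raise InputError("weight matrix must be finite")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    W0 = np.where(W > 0, W, 0.0)
    W1 = np.where(W < 0, -W, 0.0)
    s0 = W0.sum()
    s1 = W1.sum()
    if s0 > _EPS:
        k0 = W0.sum(axis=1)
        B0 = W0 - gamma * np.outer(k0, k0) / s0
    else:
        B0 = np.zeros_like(W)
    if s1 > _EPS:
        k1 = W1.sum(axis=1)
        B1 = W1 - gamma * np.outer(k1, k1) / s1
    else:
        B1 = np.zeros_like(W)
    if scheme == "negative_asym":
        denom_neg = s0 + s1
    elif scheme == "negative_sym":
        denom_neg = s1 if s1 > _EPS else 1.0
    else:
        raise InputError(f"unknown negative-weight scheme {scheme!r}")
    if s0 <= _EPS and s1 <= _EPS:
        return np.zeros_like(W)
    B = B0 / max(s0, _EPS)
    if s1 > _EPS:
        B = B - B1 / denom_neg
    return (B + B.T) / 2.0


def _one_level(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy local node moves on modularity matrix B; returns labels."""
    n = B.shape[0]
    labels = np.arange(n)
    onehot = np.eye(n)
    Hnm = B @ onehot  # node x module gains
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            current = labels[i]
            gains = Hnm[i] - Hnm[i, current] + B[i, i]
            gains[current] = 0.0
            best = int(np.argmax(gains))
            if gains[best] > 1e-10:
                Hnm[:, current] -= B[:, i]
                Hnm[:, best] += B[:, i]
                labels[i] = best
                improved = True
    return labels


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    comms = np.unique(labels)
    onehot = (labels[:, None] == comms[None, :]).astype(float)
    return onehot.T @ B @ onehot


def _partition_q(B: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def louvain_communities(
    weights: np.ndarray,
    gamma: float = 1.0,
    scheme: str = "negative_asym",
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """One Louvain run: returns (Q, labels), labels relabelled 0..k-1."""
    rng = np.random.default_rng(seed)
    B = signed_modularity_matrix(weights, gamma=gamma, scheme=scheme)
    n = B.shape[0]
    labels = np.arange(n)
    level_B = B
    while True:
        level_labels = _one_level(level_B, rng)
        comms, compact = np.unique(level_labels, return_inverse=True)
        labels = compact[labels]
        if len(comms) == level_B.shape[0]:
            break
        level_B = _aggregate(level_B, compact)
    _, labels = np.unique(labels, return_inverse=True)
    return _partition_q(B, labels), labels


def best_louvain(
    weights: np.ndarray,
    runs: int = 100,
    gamma: float = 1.0,
    scheme: str = "negative_asym",
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Run Louvain ``runs`` times with seed-derived substreams; keep max Q."""
    ss = np.random.SeedSequence(seed)
    best_q, best_labels = -np.inf, None
    for child in ss.spawn(runs):
        q, labels = louvain_communities(
            weights, gamma=gamma, scheme=scheme,
            seed=np.random.default_rng(child),
        )
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
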
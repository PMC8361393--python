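"""Graph metrics: node strength, Louvain modularity, participation.

Node strength s_i = sum_j A_ij is the headline nodal metric; normalized
strength is its within-patient z-score. Community structure comes from
best-of-n Louvain modularity maximization with the standard Newman-Girvan
quality

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i * k_j / (2m)] * delta(c_i, c_j)

extended asymmetrically for signed matrices (distance-corrected residual
networks): Q = Q+ - (v-/(v+ + v-)) * Q-, where Q+ and Q- are the positive-
and negative-part modularities and v+/v- the corresponding total weights.
The participation coefficient P_i = 1 - sum_s (kappa_is / k_i)^2 measures how
evenly a node's (positive) strength spreads across modules.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np

from .types import InvalidSpecError, Partition

logger = logging.getLogger(__name__)


def node_strength(adjacency: np.ndarray) -> np.ndarray:
    """Node strength s_i = sum_j A_ij (signed sum for residual networks)."""
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1)


def normalized_strength(strengths: np.ndarray) -> np.ndarray:
    """Within-patient z-score of node strengths (sample SD, ddof=1).

    Constant strengths yield all zeros (flagged with a warning).
    """
    s = np.asarray(strengths, dtype=float)
    if s.size < 2:
        raise InvalidSpecError("normalized strength needs at least 2 nodes")
    sd = np.std(s, ddof=1)
    if sd == 0:
        warnings.warn("constant node strengths: normalized strength set to 0")
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def _signed_parts(a: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float, float]:
    pos = np.clip(a, 0.0, None)
    neg = np.clip(-a, 0.0, None)
    return pos, neg, float(pos.sum()), float(neg.sum())


def _part_quality(a: np.ndarray, labels: np.ndarray, gamma: float, v: float) -> float:
    if v <= 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        m = labels == c
        q += a[np.ix_(m, m)].sum() - gamma * k[m].sum() ** 2 / v
    return q / v


def modularity(a: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Quality of a partition; signed asymmetric extension when A has negatives."""
    a = np.asarray(a, dtype=float)
    labels = np.asarray(labels)
    pos, neg, vp, vn = _signed_parts(a)
    qp = _part_quality(pos, labels, gamma, vp)
    if vn == 0:
        return qp
    qn = _part_quality(neg, labels, gamma, vn)
    return qp - vn / (vp + vn) * qn


def _louvain_move_pass(
    pos: np.ndarray,
    neg: np.ndarray,
    labels: np.ndarray,
    gamma: float,
    vp: float,
    vn: float,
    rng: np.random.Generator,
) -> bool:
    """One local-moving phase; mutates ``labels``. Returns True if any move."""
    n = pos.shape[0]
    if vp == 0 and vn == 0:
        return False
    alpha = vn / (vp + vn) if (vp + vn) > 0 else 0.0
    kp = pos.sum(axis=1)
    kn = neg.sum(axis=1)
    n_comm = labels.max() + 1
    sig_p = np.bincount(labels, weights=kp, minlength=n_comm)
    sig_n = np.bincount(labels, weights=kn, minlength=n_comm)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            a = labels[i]
            # connection strength of i into each community, excluding itself
            row_p = pos[i].copy()
            row_n = neg[i].copy()
            row_p[i] = 0.0
            row_n[i] = 0.0
            s_p = np.bincount(labels, weights=row_p, minlength=n_comm)
            s_n = np.bincount(labels, weights=row_n, minlength=n_comm)
            sig_p_wo = sig_p.copy()
            sig_n_wo = sig_n.copy()
            sig_p_wo[a] -= kp[i]
            sig_n_wo[a] -= kn[i]
            gain_p = (s_p - gamma * kp[i] * sig_p_wo / vp) / vp if vp > 0 else 0.0
            gain_n = (s_n - gamma * kn[i] * sig_n_wo / vn) / vn if vn > 0 else 0.0
            gain = gain_p - alpha * gain_n
            gain = gain - gain[a]
            best = int(np.argmax(gain))
            if gain[best] > 1e-12 and best != a:
                labels[i] = best
                sig_p[a] -= kp[i]
                sig_n[a] -= kn[i]
                sig_p[best] += kp[i]
                sig_n[best] += kn[i]
                moved = True
                improved = True
    return improved


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, contiguous = np.unique(labels, return_inverse=True)
    return contiguous


def _louvain_once(
    a: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """One full multi-level Louvain run; returns node labels on the input graph."""
    n = a.shape[0]
    node_labels = np.arange(n)
    level = a.copy()
    while True:
        pos, neg, vp, vn = _signed_parts(level)
        labels = np.arange(level.shape[0])
        improved = _louvain_move_pass(pos, neg, labels, gamma, vp, vn, rng)
        labels = _relabel(labels)
        if not improved or labels.max() + 1 == level.shape[0]:
            break
        node_labels = labels[node_labels]
        # aggregate: communities become nodes, within-community weight
        # becomes a self-loop
        k = labels.max() + 1
        member = np.zeros((level.shape[0], k))
        member[np.arange(level.shape[0]), labels] = 1.0
        level = member.T @ level @ member
        if k == 1:
            break
    return _relabel(node_labels)


def louvain_partition(
    adjacency: np.ndarray,
    gamma: float = 1.0,
    n_runs: int = 100,
    seed: Optional[int] = 0,
) -> Partition:
    """Best-of-``n_runs`` Louvain modularity maximization.

    Deterministic given ``seed`` (node visiting order is the only stochastic
    element); ties between runs break toward the first-found partition.
    Signed matrices are handled with the asymmetric signed quality.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidSpecError("adjacency must be square")
    if a.shape[0] == 0:
        raise InvalidSpecError("empty graph")
    if not np.allclose(a, a.T):
        raise InvalidSpecError("adjacency must be symmetric")
    rng = np.random.default_rng(seed)
    best_labels = None
    best_q = -np.inf
    for _ in range(n_runs):
        labels = _louvain_once(a, gamma, rng)
        q = modularity(a, labels, gamma)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    labels = _relabel(best_labels)
    return Partition(
        labels=labels,
        q=float(best_q),
        gamma=gamma,
        n_communities=int(labels.max() + 1),
        seed=seed,
    )


def participation_coefficient(
    adjacency: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_s (kappa_is / k_i)^2.

    kappa_is is node i's strength into module s and k_i its total strength;
    nodes with k_i = 0 get P_i = 0. For signed matrices only the positive
    part is used, keeping P in [0, 1).
    """
    a = np.clip(np.asarray(adjacency, dtype=float), 0.0, None)
    labels = np.asarray(labels)
    if labels.shape[0] != a.shape[0]:
        raise InvalidSpecError("partition does not cover all nodes")
    n_comm = int(labels.max()) + 1
    member = np.zeros((a.shape[0], n_comm))
    member[np.arange(a.shape[0]), labels] = 1.0
    kappa = a @ member
    k = kappa.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kappa / k[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    return np.where(k > 0, p, 0.0)


def patient_participation_summary(p: np.ndarray) -> float:
    """Per-patient participation summary: the median across nodes."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise InvalidSpecError("no nodes")
    return float(np.median(p))


def participation_summaries(p: np.ndarray) -> dict:
    """Median (headline) and mean node-level participation for one patient."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise InvalidSpecError("no nodes")
    return {"median": float(np.median(p)), "mean": float(np.mean(p))}
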
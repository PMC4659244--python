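"""Detection of genes with a hidden common cause, and their greedy clustering.

Every conditional distribution in the assumed model is biased: given any
parent configuration, one state has probability ``p_bias``.  When a gene's
parents are correctly recovered, its ML-estimated bias should sit near the
expected value; when its true parent is hidden, the learner substitutes
siblings or the hidden node's parents, diluting the association and pulling
the estimated bias away from expectation.  Genes whose estimated bias
deviates by more than the tolerance ``rho`` are *candidates* for having a
hidden parent.

Candidates are grouped by a single greedy pass: each candidate joins the
most-similar existing cluster center if the time-shifted G² similarity
reaches ``S0``, else it seeds a new cluster; the maximizing shift is recorded
as the member's offset relative to its cluster center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .citest import series_similarity
from .network import TransitionNetwork
from .timeseries import TimeSeriesSet

__all__ = [
    "BiasReport",
    "ClusterSet",
    "estimate_gene_bias",
    "expected_bias",
    "find_candidates",
    "greedy_cluster",
]


@dataclass
class BiasReport:
    biases: dict[int, float | None]
    expected: float
    rho: float
    candidates: list[int]


@dataclass
class ClusterSet:
    clusters: list[list[int]] = field(default_factory=list)
    centers: list[int] = field(default_factory=list)
    shifts: dict[int, int] = field(default_factory=dict)
    threshold: float = 2.3

    def sized_at_least(self, k: int) -> list[int]:
        return [i for i, c in enumerate(self.clusters) if len(c) >= k]


def estimate_gene_bias(
    data: TimeSeriesSet,
    net: TransitionNetwork,
    gene: int,
    min_config_count: int = 1,
) -> float | None:
    """Median over observed parent configurations of the conditional maximum
    probability ``max_j P(gene = j | parents = Q)``.

    Configurations observed fewer than ``min_config_count`` times are left
    out of the median; a parentless gene contributes the maximum of its
    marginal distribution.  Returns None when no configuration is usable.
    """
    parents = sorted(net.parents_of(gene))
    specs = [(p, tau) for p, tau in parents] + [(gene, 0)]
    try:
        M = data.shifted_columns(specs)
    except ValueError:
        return None
    n_s = data.n_states
    n_p = len(parents)
    strides = n_s ** np.arange(n_p - 1, -1, -1) if n_p else np.zeros(0, dtype=np.int64)
    cfg_idx = M[:, :n_p] @ strides if n_p else np.zeros(M.shape[0], dtype=np.int64)
    combined = cfg_idx.astype(np.int64) * n_s + M[:, n_p]
    counts = np.bincount(combined, minlength=(n_s**n_p) * n_s).reshape(-1, n_s)
    totals = counts.sum(axis=1)
    usable = totals >= max(min_config_count, 1)
    if not usable.any():
        return None
    maxima = counts[usable].max(axis=1) / totals[usable]
    return float(np.median(maxima))


def expected_bias(biases: dict[int, float | None], given: float | None = None) -> float:
    """The expected dominant-state probability: the supplied value when the
    bias is known, otherwise the median of the per-gene estimates."""
    if given is not None:
        return float(given)
    vals = [b for b in biases.values() if b is not None]
    if not vals:
        raise ValueError("no defined per-gene bias to estimate the expected bias from")
    return float(np.median(vals))


def find_candidates(
    biases: dict[int, float | None], expected: float, rho: float = 0.05
) -> list[int]:
    """Genes whose estimated bias deviates from expectation by more than rho."""
    return sorted(
        g for g, b in biases.items() if b is not None and abs(b - expected) > rho
    )


def greedy_cluster(
    candidates: list[int],
    data: TimeSeriesSet,
    s0: float = 2.3,
    d: int = 4,
    order: str = "index",
    rng: np.random.Generator | None = None,
) -> ClusterSet:
    """Single greedy pass over the candidates.

    The first candidate seeds cluster 1 with shift 0.  Each later candidate
    joins the cluster whose *center* maximizes the time-shifted similarity,
    provided that similarity reaches ``s0``; ties across centers go to the
    lowest cluster index.  Otherwise it seeds a new cluster.  ``order``
    selects the processing order: ``"index"`` (ascending gene id) or
    ``"random"`` (a permutation drawn from ``rng``).
    """
    cs = ClusterSet(threshold=s0)
    if not candidates:
        return cs
    seq = sorted(candidates)
    if order == "random":
        if rng is None:
            raise ValueError("order='random' requires an rng")
        seq = [seq[i] for i in rng.permutation(len(seq))]
    elif order != "index":
        raise ValueError(f"unknown order {order!r}")
    cs.clusters.append([seq[0]])
    cs.centers.append(seq[0])
    cs.shifts[seq[0]] = 0
    for g in seq[1:]:
        best_j, best_score, best_shift = -1, -np.inf, 0
        for j, center in enumerate(cs.centers):
            score, shift = series_similarity(data, center, g, d)
            if score > best_score:
                best_j, best_score, best_shift = j, score, shift
        if best_score >= s0:
            cs.clusters[best_j].append(g)
            cs.shifts[g] = best_shift
        else:
            cs.clusters.append([g])
            cs.centers.append(g)
            cs.shifts[g] = 0
    return cs
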
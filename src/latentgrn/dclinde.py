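"""Two-stage constraint-based learner for delayed discrete networks.

Stage 1 scores every ordered gene pair at every delay ``1..d`` with a G² test
and keeps the links whose score (``-log10 p``) reaches the threshold (default
2, i.e. ``p <= 0.01``); a pair may keep several delays.  Stage 2 removes
indirect effects in the spirit of the PC algorithm: for growing conditioning
sizes ``h = 1..N0`` it re-tests each surviving link conditioned on size-``h``
subsets of the link's stage-1 neighbourhood, each neighbour time-shifted
according to its stage-1 delay, and prunes the link as soon as one test fails
to reject independence.

The learner is deterministic: given the same data and parameters it returns
the same network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .citest import g2_test, pair_delay_score
from .network import ConditionalTable, DelayedEdge, TransitionNetwork
from .timeseries import TimeSeriesSet

__all__ = ["DclindeParams", "DClindeLearner", "stage1", "stage2", "learn", "fit_cpts"]


def _norm_forbidden(pairs) -> frozenset[frozenset[int]]:
    return frozenset(frozenset(p) for p in (pairs or ()))


@dataclass
class DclindeParams:
    """Learner settings.

    ``extended_from`` / ``extended_max_delay`` widen the delay search for
    pairs touching genes with id >= ``extended_from``: an estimated hidden
    series is suffix-shifted to precede its children, which pushes its true
    delays beyond ``max_delay`` (up to ``2*max_delay + 1``).
    """

    max_delay: int = 4
    score_threshold: float = 2.0
    n0: int = 2
    forbidden_pairs: frozenset = field(default_factory=frozenset)
    allow_self: bool = False
    extended_from: int | None = None
    extended_max_delay: int | None = None

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        if self.n0 < 0 or self.max_delay < 1:
            raise ValueError("need n0 >= 0 and max_delay >= 1")
        self.forbidden_pairs = _norm_forbidden(self.forbidden_pairs)

    def delay_cap(self, i: int, j: int) -> int:
        if self.extended_from is not None and (
            i >= self.extended_from or j >= self.extended_from
        ):
            return self.extended_max_delay or (2 * self.max_delay + 1)
        return self.max_delay


def stage1(data: TimeSeriesSet, params: DclindeParams) -> dict[DelayedEdge, float]:
    """Score all (i, j, tau) links; keep those with score >= threshold."""
    n = data.n_genes
    out: dict[DelayedEdge, float] = {}
    for i in range(n):
        for j in range(n):
            if i == j and not params.allow_self:
                continue
            if frozenset((i, j)) in params.forbidden_pairs:
                continue
            for tau in range(1, params.delay_cap(i, j) + 1):
                res = pair_delay_score(data, i, j, tau)
                if res.score >= params.score_threshold:
                    out[DelayedEdge(i, j, tau)] = res.score
    return out


def _conditioning_shift(
    k: int,
    i: int,
    j: int,
    tau: int,
    best: dict[tuple[int, int], tuple[int, float]],
) -> int | None:
    """Time shift of neighbour ``k`` relative to target ``j`` at shift 0.

    Preference order: k's stage-1 delay toward j; else its delay toward i
    plus ``tau``; else the reverse edges, negated accordingly.
    """
    if (k, j) in best:
        return best[(k, j)][0]
    if (k, i) in best:
        return best[(k, i)][0] + tau
    if (j, k) in best:
        return -best[(j, k)][0]
    if (i, k) in best:
        return tau - best[(i, k)][0]
    return None


def stage2(
    edges: dict[DelayedEdge, float],
    data: TimeSeriesSet,
    params: DclindeParams,
) -> set[DelayedEdge]:
    """Prune stage-1 links that turn independent given up to N0 shifted
    neighbours.  Returns the surviving edge set (a subset of stage 1)."""
    surviving = set(edges)
    for h in range(1, params.n0 + 1):
        # freeze neighbourhoods and delay lookups at the start of the level
        frozen = set(surviving)
        best: dict[tuple[int, int], tuple[int, float]] = {}
        for e in frozen:
            key = (e.src, e.dst)
            if key not in best or edges[e] > best[key][1]:
                best[key] = (e.delay, edges[e])
        nbrs: dict[int, set[int]] = {}
        for e in frozen:
            nbrs.setdefault(e.src, set()).add(e.dst)
            nbrs.setdefault(e.dst, set()).add(e.src)
        for e in sorted(frozen):
            if e not in surviving:
                continue
            i, j, tau = e.src, e.dst, e.delay
            neigh = sorted((nbrs.get(i, set()) | nbrs.get(j, set())) - {i, j})
            if len(neigh) < h:
                continue
            pruned = False
            for subset in itertools.combinations(neigh, h):
                shifts = [_conditioning_shift(k, i, j, tau, best) for k in subset]
                if any(s is None for s in shifts):
                    continue
                specs = [(i, tau), (j, 0)] + [
                    (k, int(s)) for k, s in zip(subset, shifts)
                ]
                try:
                    M = data.shifted_columns(specs)
                except ValueError:
                    continue  # no overlap at these shifts: no evidence either way
                res = g2_test(M[:, 0], M[:, 1], cond=[M[:, 2 + m] for m in range(h)])
                if res.score < params.score_threshold:
                    pruned = True
                    break
            if pruned:
                surviving.discard(e)
    return surviving


def fit_cpts(
    edges: set[DelayedEdge] | list[DelayedEdge],
    data: TimeSeriesSet,
    n_genes: int | None = None,
) -> dict[int, ConditionalTable]:
    """Maximum-likelihood CPTs on shift-aligned data (add-zero counts;
    unobserved parent configurations fall back to a uniform row)."""
    n = n_genes if n_genes is not None else data.n_genes
    n_s = data.n_states
    by_dst: dict[int, list[tuple[int, int]]] = {j: [] for j in range(n)}
    for e in edges:
        by_dst[e.dst].append((e.src, e.delay))
    cpts: dict[int, ConditionalTable] = {}
    for j in range(n):
        parents = sorted(by_dst[j])
        specs = [(p, tau) for p, tau in parents] + [(j, 0)]
        M = data.shifted_columns(specs)
        n_p = len(parents)
        table: dict[tuple[int, ...], np.ndarray] = {}
        strides = n_s ** np.arange(n_p - 1, -1, -1) if n_p else np.zeros(0, dtype=np.int64)
        cfg_idx = M[:, :n_p] @ strides if n_p else np.zeros(M.shape[0], dtype=np.int64)
        combined = cfg_idx * n_s + M[:, n_p]
        counts = np.bincount(combined.astype(np.int64), minlength=(n_s**n_p) * n_s)
        counts = counts.reshape(n_s**n_p, n_s)
        for flat in range(n_s**n_p):
            cfg = tuple((flat // n_s**k) % n_s for k in range(n_p - 1, -1, -1))
            tot = counts[flat].sum()
            row = counts[flat] / tot if tot > 0 else np.full(n_s, 1.0 / n_s)
            table[cfg] = row
        cpts[j] = ConditionalTable(parent_list=parents, table=table)
    return cpts


def learn(data: TimeSeriesSet, params: DclindeParams | None = None) -> TransitionNetwork:
    """Run both stages and fit ML CPTs; all genes treated as observed."""
    params = params or DclindeParams()
    s1 = stage1(data, params)
    final = stage2(s1, data, params)
    net = TransitionNetwork(
        n_obs=data.n_genes,
        hidden_ids=set(),
        edges=sorted(final),
        n_states=data.n_states,
        max_delay=params.max_delay,
    )
    net.cpts = fit_cpts(final, data, n_genes=data.n_genes)
    return net


def as_timeseries(X, n_states: int | None = None) -> TimeSeriesSet:
    """Coerce a TimeSeriesSet, a genes x T matrix, or a list of matrices."""
    if isinstance(X, TimeSeriesSet):
        return X
    if isinstance(X, np.ndarray) and X.ndim == 2:
        X = [X]
    series = [np.asarray(s, dtype=np.int64) for s in X]
    if n_states is None:
        n_states = int(max(s.max() for s in series)) + 1
    return TimeSeriesSet(series=series, n_states=n_states)


class DClindeLearner(BaseEstimator):
    """Sklearn-style wrapper around the two-stage delayed-network learner.

    Parameters mirror :class:`DclindeParams`.  ``fit`` accepts a
    :class:`TimeSeriesSet`, a single genes x T integer matrix, or a list of
    such matrices (multiple series).

    Attributes
    ----------
    network_ : TransitionNetwork
        The learned network with ML-fitted CPTs.
    stage1_ : dict[DelayedEdge, float]
        Scores of the links surviving stage 1.
    """

    def __init__(
        self,
        max_delay: int = 4,
        score_threshold: float = 2.0,
        n0: int = 2,
        forbidden_pairs: frozenset = frozenset(),
        allow_self: bool = False,
        n_states: int | None = None,
    ):
        self.max_delay = max_delay
        self.score_threshold = score_threshold
        self.n0 = n0
        self.forbidden_pairs = forbidden_pairs
        self.allow_self = allow_self
        self.n_states = n_states

    def _params(self) -> DclindeParams:
        return DclindeParams(
            max_delay=self.max_delay,
            score_threshold=self.score_threshold,
            n0=self.n0,
            forbidden_pairs=self.forbidden_pairs,
            allow_self=self.allow_self,
        )

    def fit(self, X, y=None):
        data = as_timeseries(X, self.n_states)
        params = self._params()
        self.stage1_ = stage1(data, params)
        final = stage2(self.stage1_, data, params)
        self.network_ = TransitionNetwork(
            n_obs=data.n_genes,
            hidden_ids=set(),
            edges=sorted(final),
            n_states=data.n_states,
            max_delay=params.max_delay,
        )
        self.network_.cpts = fit_cpts(final, data, n_genes=data.n_genes)
        self.n_features_in_ = data.n_genes
        return self

    def transform(self, X=None):
        """Return the learned edge list as an (n_edges, 3) array."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        return np.array(
            [(e.src, e.dst, e.delay) for e in sorted(self.network_.edges)], dtype=np.int64
        ).reshape(-1, 3)
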
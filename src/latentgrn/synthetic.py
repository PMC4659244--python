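"""Benchmark generators: synthetic networks and expression data.

Three network families are generated, mirroring the benchmark study
conditions:

* **Case I** — a small network with one hidden hub: ``p >= 0`` observed
  parents feeding the hidden node and ``c >= 2`` observed children fed by it.
* **Case II** — a small all-observed network: the structure a learner infers
  from incomplete case-I data (a plausible-but-wrong network), or, when that
  is empty, a hub with ``p`` parents and ``c - 1`` children.
* **Case III** — a larger network (50 or 100 observed genes) with
  ``ceil(n/10)`` hidden nodes and four node roles: hidden, parents of hidden,
  children of hidden, and other.

Delays are i.i.d. uniform on ``{1..d}``; every conditional distribution is
biased (dominant state ``p_bias``, the rest sharing the remainder equally).
Data simulation draws ``d`` uniform burn-in points (discarded) and then
samples each node from its CPT given the delayed parent states; short series
have lengths uniform on ``{20..35}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ConditionalTable, TransitionNetwork, all_configs, make_biased_cpt
from .timeseries import TimeSeriesSet

__all__ = [
    "GenConfig",
    "gen_case1_network",
    "gen_case2_network",
    "gen_case3_network",
    "simulate_series",
    "simulate_short_series",
    "generate_dataset",
]

SHORT_SERIES_MIN = 20
SHORT_SERIES_MAX = 35


@dataclass
class GenConfig:
    """Parameters of synthetic generation (one benchmark grid point)."""

    case: str  # "I", "II" or "III"
    p: int = 0
    c: int = 2
    n_obs: int = 50
    p_bias: float = 0.75
    n_states: int = 3
    max_delay: int = 4
    series_mode: str = "long"  # "long" or "short"
    T: int = 800
    K: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in {"I", "II", "III"}:
            raise ValueError(f"unknown case {self.case!r}")
        if self.case in {"I", "II"}:
            if not (0 <= self.p <= 3 and 2 <= self.c <= 5):
                raise ValueError("case I/II requires p in 0..3 and c in 2..5")
        if self.series_mode not in {"long", "short"}:
            raise ValueError("series_mode must be 'long' or 'short'")

    @property
    def n_hidden_case3(self) -> int:
        return math.ceil(self.n_obs / 10)


def _biased_cpts_for(net: TransitionNetwork, p_bias: float, rng: np.random.Generator) -> None:
    """Attach a biased CPT to every node of ``net`` given its parents."""
    for node in net.node_ids():
        parents = sorted(net.parents_of(node))
        cfgs = all_configs(net.n_states, len(parents))
        net.cpts[node] = make_biased_cpt(net.n_states, p_bias, cfgs, rng, parent_list=parents)


def gen_case1_network(cfg: GenConfig, rng: np.random.Generator) -> TransitionNetwork:
    """One hidden node with ``p`` observed parents and ``c`` observed children."""
    if cfg.case != "I":
        raise ValueError("cfg.case must be 'I'")
    n_obs = cfg.p + cfg.c
    h = n_obs
    net = TransitionNetwork(
        n_obs=n_obs, hidden_ids={h}, n_states=cfg.n_states, max_delay=cfg.max_delay
    )
    for par in range(cfg.p):
        net.add_edge(par, h, int(rng.integers(1, cfg.max_delay + 1)))
    for child in range(cfg.p, cfg.p + cfg.c):
        net.add_edge(h, child, int(rng.integers(1, cfg.max_delay + 1)))
    _biased_cpts_for(net, cfg.p_bias, rng)
    return net


def gen_case2_network(
    cfg: GenConfig,
    rng: np.random.Generator,
    initial_guess: TransitionNetwork | None = None,
) -> TransitionNetwork:
    """All-observed small network: a learned guess on incomplete case-I data
    when non-empty, otherwise a hub with ``p`` parents and ``c - 1`` children."""
    if cfg.case != "II":
        raise ValueError("cfg.case must be 'II'")
    if initial_guess is not None and initial_guess.edges:
        net = TransitionNetwork(
            n_obs=initial_guess.n_obs,
            hidden_ids=set(),
            edges=list(initial_guess.edges),
            n_states=cfg.n_states,
            max_delay=cfg.max_delay,
        )
    else:
        # parents 0..p-1 -> hub p -> children p+1..p+c-1  (p + c nodes total)
        n_obs = cfg.p + cfg.c
        hub = cfg.p
        net = TransitionNetwork(
            n_obs=n_obs, hidden_ids=set(), n_states=cfg.n_states, max_delay=cfg.max_delay
        )
        for par in range(cfg.p):
            net.add_edge(par, hub, int(rng.integers(1, cfg.max_delay + 1)))
        for child in range(cfg.p + 1, cfg.p + cfg.c):
            net.add_edge(hub, child, int(rng.integers(1, cfg.max_delay + 1)))
    _biased_cpts_for(net, cfg.p_bias, rng)
    return net


def gen_case3_network(cfg: GenConfig, rng: np.random.Generator) -> TransitionNetwork:
    """Larger network with ``ceil(n/10)`` hidden nodes and disjoint node roles.

    Per hidden node: parents uniform on {0..3}, children uniform on {2..5},
    all drawn from disjoint pools of observed genes.  Parents of hidden take
    1-2 "other" genes as parents; "other" genes take 1-2 arbitrary observed
    genes as parents.
    """
    if cfg.case != "III":
        raise ValueError("cfg.case must be 'III'")
    n = cfg.n_obs
    n_h = cfg.n_hidden_case3
    n_par = [int(rng.integers(0, 4)) for _ in range(n_h)]
    n_child = [int(rng.integers(2, 6)) for _ in range(n_h)]
    need = sum(n_par) + sum(n_child)
    n_other = n - need
    if n_other < (1 if sum(n_par) > 0 else 0):
        raise ValueError(
            f"n_obs={n} too small for {n_h} hidden nodes with these role counts"
        )
    pool = list(rng.permutation(n))
    net = TransitionNetwork(
        n_obs=n,
        hidden_ids=set(range(n, n + n_h)),
        n_states=cfg.n_states,
        max_delay=cfg.max_delay,
    )
    rand_delay = lambda: int(rng.integers(1, cfg.max_delay + 1))
    parents_of_hidden: list[int] = []
    for k in range(n_h):
        h = n + k
        children = [pool.pop() for _ in range(n_child[k])]
        parents = [pool.pop() for _ in range(n_par[k])]
        parents_of_hidden.extend(parents)
        for ch in children:
            net.add_edge(h, ch, rand_delay())
        for par in parents:
            net.add_edge(par, h, rand_delay())
    other = list(pool)
    for par in parents_of_hidden:
        k = min(int(rng.integers(1, 3)), len(other))
        for src in rng.choice(other, size=k, replace=False):
            net.add_edge(int(src), par, rand_delay())
    hidden_children = {e.dst for e in net.edges if e.src in net.hidden_ids}
    candidates_pool = [g for g in range(n) if g not in hidden_children]
    for node in other:
        srcs = [g for g in candidates_pool if g != node]
        k = min(int(rng.integers(1, 3)), len(srcs))
        for src in rng.choice(srcs, size=k, replace=False):
            net.add_edge(int(src), node, rand_delay())
    _biased_cpts_for(net, cfg.p_bias, rng)
    return net


# ---------------------------------------------------------------------------
# data simulation
# ---------------------------------------------------------------------------

def _compile_sampler(net: TransitionNetwork):
    """Precompute per-node parent indices, delays, and CPT cumulative rows."""
    n_s = net.n_states
    compiled = []
    ids = net.node_ids()
    row_of = {nid: r for r, nid in enumerate(ids)}
    for nid in ids:
        cpt = net.cpts[nid]
        parents = cpt.parent_list
        n_p = len(parents)
        prow = np.array([row_of[p] for p, _ in parents], dtype=np.int64)
        pdel = np.array([tau for _, tau in parents], dtype=np.int64)
        strides = n_s ** np.arange(n_p - 1, -1, -1) if n_p else np.zeros(0, dtype=np.int64)
        cum = np.empty((n_s**n_p, n_s))
        for cfg, probs in cpt.table.items():
            idx = int(np.dot(cfg, strides)) if n_p else 0
            cum[idx] = np.cumsum(probs)
        compiled.append((prow, pdel, strides.astype(np.int64), cum))
    return compiled


def simulate_series(
    net: TransitionNetwork, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one series of ``T`` points over **all** nodes (observed rows
    first, hidden rows after, in id order).

    ``d`` uniform burn-in points seed the delayed dependencies and are
    discarded from the output.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    d = net.max_delay
    n_nodes = net.n_nodes
    n_s = net.n_states
    compiled = _compile_sampler(net)
    x = np.empty((n_nodes, d + T), dtype=np.int64)
    x[:, :d] = rng.integers(0, n_s, size=(n_nodes, d))
    # one uniform draw per node per step, in time order, so that a shorter
    # run is a prefix of a longer one under the same seed
    for t in range(d, d + T):
        u = rng.random(n_nodes)
        col = x[:, t]
        for r in range(n_nodes):
            prow, pdel, strides, cum = compiled[r]
            idx = int(np.dot(x[prow, t - pdel], strides)) if prow.size else 0
            col[r] = np.searchsorted(cum[idx], u[r], side="right")
    return x[:, d:]


def simulate_short_series(
    net: TransitionNetwork, K: int, rng: np.random.Generator
) -> TimeSeriesSet:
    """K independent series with lengths uniform on {20..35}."""
    if K < 1:
        raise ValueError("K must be >= 1")
    series = []
    for _ in range(K):
        T = int(rng.integers(SHORT_SERIES_MIN, SHORT_SERIES_MAX + 1))
        series.append(simulate_series(net, T, rng))
    return TimeSeriesSet(series=series, n_states=net.n_states)


def _observed_view(ts: TimeSeriesSet, n_obs: int) -> TimeSeriesSet:
    return TimeSeriesSet([s[:n_obs, :] for s in ts.series], n_states=ts.n_states)


def generate_dataset(
    cfg: GenConfig, rng: np.random.Generator
) -> tuple[TransitionNetwork, TimeSeriesSet, TimeSeriesSet]:
    """Generate (truth network, complete data, observed-only data) for one
    replicate of the configured case and series mode.

    Case II first generates a case-I network, simulates incomplete data
    (800 points, matching the long-series budget), learns an all-observed
    guess with the two-stage learner, and uses it (or the fallback hub) as
    the truth.
    """
    if cfg.case == "I":
        net = gen_case1_network(cfg, rng)
    elif cfg.case == "III":
        net = gen_case3_network(cfg, rng)
    else:
        from .dclinde import DclindeParams, learn  # lazy: avoids import cycle

        case1 = GenConfig(
            case="I",
            p=cfg.p,
            c=cfg.c,
            p_bias=cfg.p_bias,
            n_states=cfg.n_states,
            max_delay=cfg.max_delay,
            series_mode="long",
            T=800,
        )
        pre_net = gen_case1_network(case1, rng)
        pre_full = simulate_series(pre_net, 800, rng)
        pre_obs = TimeSeriesSet([pre_full[: pre_net.n_obs]], n_states=cfg.n_states)
        guess = learn(pre_obs, DclindeParams(max_delay=cfg.max_delay))
        net = gen_case2_network(cfg, rng, initial_guess=guess)

    if cfg.series_mode == "long":
        full = TimeSeriesSet([simulate_series(net, cfg.T, rng)], n_states=cfg.n_states)
    else:
        full = simulate_short_series(net, cfg.K, rng)
    return net, full, _observed_view(full, net.n_obs)
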
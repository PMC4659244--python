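"""Transition-network representation of a stationary d-th order discrete DBN.

The transition network is a delayed multigraph: an edge ``i -> j`` with delay
``tau >= 1`` means gene ``j`` at time ``t`` depends on gene ``i`` at time
``t - tau``.  Multiple edges between the same ordered pair are allowed as long
as their delays differ.  Each node carries a conditional probability table
(CPT) over its parents' joint configuration; generator-built CPTs are *biased*:
one dominant state receives probability ``p_bias`` and the remaining states
share ``(1 - p_bias) / (n_states - 1)`` equally.

Hidden nodes are ordinary nodes flagged in ``hidden_ids``; by convention they
occupy ids ``>= n_obs``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DelayedEdge",
    "ConditionalTable",
    "TransitionNetwork",
    "make_biased_cpt",
]


@dataclass(frozen=True, order=True)
class DelayedEdge:
    """Directed edge ``src -> dst`` with a positive time delay."""

    src: int
    dst: int
    delay: int

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError(f"intra-slice edge (delay={self.delay}); delays must be >= 1")


@dataclass
class ConditionalTable:
    """CPT of one node: P(node | parents at their delays).

    ``parent_list`` is an ordered list of ``(parent_id, delay)``; ``table``
    maps each parent configuration (tuple of parent states, ``()`` for a
    parentless node) to a probability vector over the node's states.
    """

    parent_list: list[tuple[int, int]]
    table: dict[tuple[int, ...], np.ndarray]

    def n_states(self) -> int:
        return len(next(iter(self.table.values())))

    def check(self) -> None:
        for cfg, probs in self.table.items():
            if len(cfg) != len(self.parent_list):
                raise ValueError("configuration arity mismatch")
            if abs(float(np.sum(probs)) - 1.0) > 1e-9:
                raise ValueError(f"probability row for {cfg} does not sum to 1")


def make_biased_cpt(
    n_s: int,
    p_bias: float,
    parent_configs: list[tuple[int, ...]],
    rng: np.random.Generator,
    parent_list: list[tuple[int, int]] | None = None,
) -> ConditionalTable:
    """Build a biased CPT: per configuration a uniformly chosen dominant state
    gets ``p_bias``; the other ``n_s - 1`` states split the remaining mass.

    ``p_bias`` must strictly exceed ``1 / n_s`` so the dominant state is
    actually dominant.
    """
    if n_s < 2:
        raise ValueError("need at least 2 states")
    if not parent_configs:
        raise ValueError("parent_configs must be non-empty (use [()] for parentless nodes)")
    if p_bias <= 1.0 / n_s:
        raise ValueError(f"p_bias={p_bias} is not dominant for n_s={n_s} (must exceed 1/n_s)")
    other = (1.0 - p_bias) / (n_s - 1)
    table: dict[tuple[int, ...], np.ndarray] = {}
    for cfg in parent_configs:
        dom = int(rng.integers(n_s))
        row = np.full(n_s, other)
        row[dom] = p_bias
        table[tuple(cfg)] = row
    return ConditionalTable(parent_list=list(parent_list or []), table=table)


def all_configs(n_s: int, n_parents: int) -> list[tuple[int, ...]]:
    """Every joint parent configuration, ``[()]`` when there are no parents."""
    return [tuple(c) for c in itertools.product(range(n_s), repeat=n_parents)]


@dataclass
class TransitionNetwork:
    """Delayed multigraph over observed + hidden nodes with per-node CPTs."""

    n_obs: int
    hidden_ids: set[int] = field(default_factory=set)
    edges: list[DelayedEdge] = field(default_factory=list)
    n_states: int = 3
    max_delay: int = 4
    cpts: dict[int, ConditionalTable] = field(default_factory=dict)

    # -- basic structure queries -------------------------------------------
    @property
    def n_hidden(self) -> int:
        return len(self.hidden_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_obs + self.n_hidden

    def node_ids(self) -> list[int]:
        return list(range(self.n_obs)) + sorted(self.hidden_ids)

    def parents_of(self, node: int) -> list[tuple[int, int]]:
        return [(e.src, e.delay) for e in self.edges if e.dst == node]

    def children_of(self, node: int) -> list[int]:
        return sorted({e.dst for e in self.edges if e.src == node})

    def add_edge(self, src: int, dst: int, delay: int) -> None:
        e = DelayedEdge(src, dst, delay)
        if e in self.edges:
            raise ValueError(f"duplicate edge {e}")
        self.edges.append(e)

    def edge_multiset(self) -> set[DelayedEdge]:
        return set(self.edges)

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Check the structural assumptions; returns violation descriptions.

        Assumptions checked: hidden count bounds (2), no intra-slice edges (3),
        every hidden node has >= 2 observed children (4), a gene with a hidden
        parent has no other parent (5), no link between co-children of one
        hidden node (6), and CPT rows are proper distributions (7).
        """
        out: list[str] = []
        if not (0 <= self.n_hidden < max(self.n_obs, 1)):
            out.append(f"assumption 2: n_h={self.n_hidden} not in [0, n_obs={self.n_obs})")
        for h in self.hidden_ids:
            if h < self.n_obs:
                out.append(f"hidden id {h} < n_obs={self.n_obs} (convention: hidden ids >= n_obs)")
        seen: set[DelayedEdge] = set()
        for e in self.edges:
            if e in seen:
                out.append(f"duplicate edge {e}")
            seen.add(e)
            if e.delay < 1:
                out.append(f"intra-slice edge {e}")
        pairs = {(e.src, e.dst) for e in self.edges}
        for h in self.hidden_ids:
            kids = [d for (s, d) in pairs if s == h]
            obs_kids = [k for k in kids if k not in self.hidden_ids]
            if len(set(obs_kids)) < 2:
                out.append(f"assumption 4: hidden node {h} has {len(set(obs_kids))} observed children")
            for p, _ in [(s, d) for (s, d) in pairs if d == h]:
                if p in self.hidden_ids:
                    out.append(f"hidden node {h} has hidden parent {p}")
            for a in set(kids):
                others = {s for (s, d) in pairs if d == a and s != h}
                if others:
                    out.append(
                        f"assumption 5: gene {a} has hidden parent {h} and other parents {sorted(others)}"
                    )
            for a, b in itertools.combinations(sorted(set(kids)), 2):
                if (a, b) in pairs or (b, a) in pairs:
                    out.append(f"assumption 6: co-children {a},{b} of hidden {h} are linked")
        for node, cpt in self.cpts.items():
            try:
                cpt.check()
            except ValueError as exc:  # pragma: no cover - defensive
                out.append(f"assumption 7: CPT of node {node}: {exc}")
        return out

    # -- views -------------------------------------------------------------
    def observed_subnetwork(self) -> "TransitionNetwork":
        """Drop hidden nodes and all incident edges (the 'incomplete' view)."""
        keep = [e for e in self.edges if e.src not in self.hidden_ids and e.dst not in self.hidden_ids]
        cpts = {n: c for n, c in self.cpts.items() if n not in self.hidden_ids}
        return TransitionNetwork(
            n_obs=self.n_obs,
            hidden_ids=set(),
            edges=list(keep),
            n_states=self.n_states,
            max_delay=self.max_delay,
            cpts=cpts,
        )

    # -- serialization -----------------------------------------------------
    def to_edgelist(self) -> str:
        """One line per edge: ``src dst delay`` (0-based ids)."""
        lines = [f"{e.src} {e.dst} {e.delay}" for e in sorted(self.edges)]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_edgelist(
        cls,
        text: str,
        n_obs: int,
        hidden_ids: set[int] | None = None,
        n_states: int = 3,
        max_delay: int = 4,
    ) -> "TransitionNetwork":
        net = cls(n_obs=n_obs, hidden_ids=set(hidden_ids or ()), n_states=n_states, max_delay=max_delay)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, d, tau = (int(v) for v in line.split())
            net.add_edge(s, d, tau)
        return net

    def cpts_to_text(self) -> str:
        """Sidecar CPT serialization: node, parent list, then one row per config."""
        chunks: list[str] = []
        for node in sorted(self.cpts):
            cpt = self.cpts[node]
            plist = ";".join(f"{p},{tau}" for p, tau in cpt.parent_list) or "-"
            chunks.append(f"node {node} parents {plist}")
            for cfg in sorted(cpt.table):
                key = ",".join(map(str, cfg)) or "-"
                row = " ".join(repr(float(v)) for v in cpt.table[cfg])
                chunks.append(f"  {key} : {row}")
        return "\n".join(chunks) + ("\n" if chunks else "")

    @staticmethod
    def cpts_from_text(text: str) -> dict[int, ConditionalTable]:
        cpts: dict[int, ConditionalTable] = {}
        node = None
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("node "):
                _, nid, _, plist = line.split()
                node = int(nid)
                parents = (
                    []
                    if plist == "-"
                    else [tuple(int(v) for v in p.split(",")) for p in plist.split(";")]
                )
                cpts[node] = ConditionalTable(parent_list=[(p, t) for p, t in parents], table={})
            else:
                key, row = line.split(":")
                key = key.strip()
                cfg = () if key == "-" else tuple(int(v) for v in key.split(","))
                cpts[node].table[cfg] = np.array([float(v) for v in row.split()])
        return cpts
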
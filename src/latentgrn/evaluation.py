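"""Links / Delays precision-recall-F scoring against a ground-truth network.

A predicted *link* is correct iff the ordered gene pair matches a true edge;
a predicted *delay* is correct iff the pair, direction and delay all match.
Because the time decomposition around a hidden node is only identifiable up
to a constant, a predicted hidden node is first mapped onto a true hidden
node together with a delay shift ``delta``: ``delta`` is added to its
outgoing delays and subtracted from its incoming delays (legal shifts keep
every delay positive).  Each predicted hidden node maps to the
``(true hidden, delta)`` with the most matched delays (ties: most matched
links, then the lowest true index, then the smallest ``|delta|``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import TransitionNetwork

__all__ = ["MetricReport", "count_matches", "map_hidden", "evaluate"]

Edge = tuple[object, object, int]  # (src, dst, delay); hidden ids may be tagged


@dataclass
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_score(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p > 0 else 0.0


@dataclass
class MetricReport:
    links: PRF
    delays: PRF
    mapping: dict[int, tuple[int, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "links": {
                "tp": self.links.tp, "fp": self.links.fp, "fn": self.links.fn,
                "recall": self.links.recall, "precision": self.links.precision,
                "f_score": self.links.f_score,
            },
            "delays": {
                "tp": self.delays.tp, "fp": self.delays.fp, "fn": self.delays.fn,
                "recall": self.delays.recall, "precision": self.delays.precision,
                "f_score": self.delays.f_score,
            },
            "hidden_mapping": {str(k): list(v) for k, v in self.mapping.items()},
        }


def _edge_tuples(net: TransitionNetwork) -> set[Edge]:
    return {(e.src, e.dst, e.delay) for e in net.edges}


def count_matches(pred_edges: set[Edge], truth_edges: set[Edge]) -> tuple[PRF, PRF]:
    """Links counted once per ordered pair; delays once per (pair, delay)."""
    pred_links = {(s, d) for s, d, _ in pred_edges}
    true_links = {(s, d) for s, d, _ in truth_edges}
    links = PRF(
        tp=len(pred_links & true_links),
        fp=len(pred_links - true_links),
        fn=len(true_links - pred_links),
    )
    delays = PRF(
        tp=len(pred_edges & truth_edges),
        fp=len(pred_edges - truth_edges),
        fn=len(truth_edges - pred_edges),
    )
    return links, delays


def _candidate_deltas(max_delay: int) -> range:
    """Delta search range; predicted hidden delays live in [1, 2*max_delay+1]
    and true delays in [1, max_delay], so this covers every useful alignment.
    A shifted delay that falls below 1 simply cannot match any true edge."""
    cap = 2 * max_delay + 1
    return range(-cap, cap + 1)


def map_hidden(
    pred: TransitionNetwork,
    truth: TransitionNetwork,
    d: int | None = None,
) -> dict[int, tuple[int, int]]:
    """Map each predicted hidden node to ``(true hidden id, delta)``.

    Only edges to/from observed genes take part in the matching.  Predicted
    hidden nodes without any true hidden node to map to are left out of the
    mapping (their edges then count as false positives).
    """
    d = d if d is not None else max(pred.max_delay, truth.max_delay)
    true_hidden = sorted(truth.hidden_ids)
    truth_edges = _edge_tuples(truth)
    mapping: dict[int, tuple[int, int]] = {}
    for ph in sorted(pred.hidden_ids):
        outs = [(e.dst, e.delay) for e in pred.edges if e.src == ph and e.dst not in pred.hidden_ids]
        ins = [(e.src, e.delay) for e in pred.edges if e.dst == ph and e.src not in pred.hidden_ids]
        best = None  # (delays_matched, links_matched, -th, -|delta|) maximized
        for th in true_hidden:
            for delta in _candidate_deltas(d):
                shifted = {(th, g, t + delta) for g, t in outs} | {
                    (g, th, t - delta) for g, t in ins
                }
                dm = len(shifted & truth_edges)
                shifted_links = {(s, dd) for s, dd, _ in shifted}
                lm = len(shifted_links & {(s, dd) for s, dd, _ in truth_edges})
                key = (dm, lm, -th, -abs(delta), -delta)
                if best is None or key > best[0]:
                    best = (key, th, delta)
        if best is not None:
            mapping[ph] = (best[1], best[2])
    return mapping


def _apply_mapping(pred: TransitionNetwork, mapping: dict[int, tuple[int, int]]) -> set[Edge]:
    edges: set[Edge] = set()
    for e in pred.edges:
        src: object = e.src
        dst: object = e.dst
        delay = e.delay
        if e.src in pred.hidden_ids:
            if e.src in mapping:
                src, delta = mapping[e.src]
                delay = delay + delta
            else:
                src = ("ph", e.src)  # unmatched predicted hidden: never matches truth
        if e.dst in pred.hidden_ids:
            if e.dst in mapping:
                dst, delta = mapping[e.dst]
                delay = delay - delta
            else:
                dst = ("ph", e.dst)
        edges.add((src, dst, delay))
    return edges


def evaluate(
    pred: TransitionNetwork,
    truth: TransitionNetwork,
    d: int | None = None,
) -> MetricReport:
    """Hidden-node mapping followed by Links/Delays PRF computation."""
    mapping = map_hidden(pred, truth, d)
    pred_edges = _apply_mapping(pred, mapping)
    links, delays = count_matches(pred_edges, _edge_tuples(truth))
    return MetricReport(links=links, delays=delays, mapping=mapping)
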
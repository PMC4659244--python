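"""The four-step inference pipeline, exposed as an sklearn-style estimator.

1. Learn an initial network on the observed genes with the two-stage learner.
2. Estimate every gene's conditional-distribution bias and flag *candidates*
   whose bias deviates from the expected bias by more than ``rho``.
3. Greedily cluster the candidates by time-shifted similarity; estimate a
   hidden common cause (state sequence) by two-round EM for every cluster
   with at least two members.
4. Relearn the network on the observed series plus the estimated hidden
   series, forbidding links between candidates of the same cluster.

Short circuits: no candidates, or no cluster of size >= 2, returns the
initial network unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .dclinde import DclindeParams, as_timeseries, learn
from .em import estimate_hidden
from .hidden import (
    BiasReport,
    ClusterSet,
    estimate_gene_bias,
    expected_bias,
    find_candidates,
    greedy_cluster,
)
from .network import TransitionNetwork
from .timeseries import TimeSeriesSet

__all__ = ["PipelineConfig", "HiddenCauseGRNLearner", "run_pipeline", "relearn"]


@dataclass
class PipelineConfig:
    dclinde: DclindeParams = field(default_factory=DclindeParams)
    p_bias: float | None = None  # None: estimate from the per-gene medians
    rho: float = 0.05
    s0: float = 2.3
    em_iters: int = 100
    hidden_states: int | None = None  # None: max of the children's state counts
    cluster_order: str = "index"  # or "random"
    min_config_count: int = 1


def relearn(
    augmented: TimeSeriesSet,
    n_obs: int,
    clusters: ClusterSet,
    cfg: PipelineConfig,
) -> TransitionNetwork:
    """Relearn on observed + hidden series, forbidding within-cluster links
    between candidates and extending the delay range for hidden pairs."""
    forbidden = set(cfg.dclinde.forbidden_pairs)
    for members in clusters.clusters:
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                forbidden.add(frozenset((a, b)))
    params = DclindeParams(
        max_delay=cfg.dclinde.max_delay,
        score_threshold=cfg.dclinde.score_threshold,
        n0=cfg.dclinde.n0,
        forbidden_pairs=frozenset(forbidden),
        allow_self=cfg.dclinde.allow_self,
        extended_from=n_obs,
        extended_max_delay=2 * cfg.dclinde.max_delay + 1,
    )
    net = learn(augmented, params)
    net.n_obs = n_obs
    net.hidden_ids = set(range(n_obs, augmented.n_genes))
    return net


def run_pipeline(
    data: TimeSeriesSet,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TransitionNetwork, dict]:
    """Run all four steps; returns the final network and a report carrying
    every intermediate artifact."""
    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng()
    d = cfg.dclinde.max_delay
    report: dict = {}

    initial = learn(data, cfg.dclinde)
    report["initial_network"] = initial

    biases = {
        g: estimate_gene_bias(data, initial, g, cfg.min_config_count)
        for g in range(data.n_genes)
    }
    exp = expected_bias(biases, cfg.p_bias)
    cands = find_candidates(biases, exp, cfg.rho)
    report["bias"] = BiasReport(biases=biases, expected=exp, rho=cfg.rho, candidates=cands)
    if not cands:
        report["short_circuit"] = "no candidates"
        return initial, report

    clusters = greedy_cluster(
        cands, data, s0=cfg.s0, d=d, order=cfg.cluster_order, rng=rng
    )
    report["clusters"] = clusters
    qualifying = clusters.sized_at_least(2)
    if not qualifying:
        report["short_circuit"] = "no cluster of size >= 2"
        return initial, report

    hidden_rows = []
    em_info = []
    for j in qualifying:
        members = [(g, clusters.shifts[g]) for g in clusters.clusters[j]]
        rows, info = estimate_hidden(
            members,
            data,
            d=d,
            em_iters=cfg.em_iters,
            n_states_hidden=cfg.hidden_states,
            rng=rng,
        )
        hidden_rows.append(rows)
        em_info.append(info)
    report["em"] = em_info
    report["hidden_series"] = hidden_rows

    augmented = data.with_rows(hidden_rows)
    final = relearn(augmented, data.n_genes, clusters, cfg)
    report["final_network"] = final
    return final, report


class HiddenCauseGRNLearner(BaseEstimator):
    """Sklearn-style estimator for the full hidden-cause-aware pipeline.

    ``fit`` accepts a :class:`TimeSeriesSet`, a genes x T integer matrix, or
    a list of such matrices.  All randomness (random clustering order, EM
    initialization and restarts) is driven by ``random_state``.

    Attributes
    ----------
    network_ : TransitionNetwork
        Final network; hidden nodes (if any) carry ids >= n_genes.
    initial_network_ : TransitionNetwork
        Step-1 network on the observed genes alone.
    bias_report_ : BiasReport
        Per-gene estimated biases, the expected bias, and the candidates.
    clusters_ : ClusterSet or None
        Candidate clustering (None when step 2 short-circuited).
    hidden_series_ : list
        Per-cluster estimated hidden series (per-series rows).
    """

    def __init__(
        self,
        max_delay: int = 4,
        score_threshold: float = 2.0,
        n0: int = 2,
        p_bias: float | None = None,
        rho: float = 0.05,
        s0: float = 2.3,
        em_iters: int = 100,
        hidden_states: int | None = None,
        cluster_order: str = "index",
        n_states: int | None = None,
        random_state: int | None = None,
    ):
        self.max_delay = max_delay
        self.score_threshold = score_threshold
        self.n0 = n0
        self.p_bias = p_bias
        self.rho = rho
        self.s0 = s0
        self.em_iters = em_iters
        self.hidden_states = hidden_states
        self.cluster_order = cluster_order
        self.n_states = n_states
        self.random_state = random_state

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            dclinde=DclindeParams(
                max_delay=self.max_delay,
                score_threshold=self.score_threshold,
                n0=self.n0,
            ),
            p_bias=self.p_bias,
            rho=self.rho,
            s0=self.s0,
            em_iters=self.em_iters,
            hidden_states=self.hidden_states,
            cluster_order=self.cluster_order,
        )

    def fit(self, X, y=None):
        data = as_timeseries(X, self.n_states)
        rng = np.random.default_rng(self.random_state)
        net, report = run_pipeline(data, self._config(), rng)
        self.network_ = net
        self.initial_network_ = report["initial_network"]
        self.bias_report_ = report["bias"]
        self.clusters_ = report.get("clusters")
        self.hidden_series_ = report.get("hidden_series", [])
        self.report_ = report
        self.n_features_in_ = data.n_genes
        return self

    def transform(self, X=None):
        """Learned edge list as an (n_edges, 3) integer array."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        return np.array(
            [(e.src, e.dst, e.delay) for e in sorted(self.network_.edges)],
            dtype=np.int64,
        ).reshape(-1, 3)
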
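"""EM estimation of a hidden common cause's discrete state sequence.

For a cluster ``C = {g_1..g_|C|}`` of candidate genes with relative shifts
``tau_i`` against the cluster center, the members are aligned on a common
reference clock (the "expanded" alignment, which keeps partially observed
time points) and a latent state ``h_t`` is estimated at every aligned time
point.  The likelihood parameters are ``theta = {P(h|Q)} u {P(g_i|h)}``
where ``Q`` is the joint configuration of the hidden node's *potential
parents* (absent in round 1, so ``P(h|Q)`` degenerates to ``P(h)``).

E-step, per time point and hidden state ``j``::

    A_{j,t} = P(h=j|Q_t) * prod_i P(g_i = x_{i,t} | h=j)      (i observed at t)
    B_{j,t} = A_{j,t} / sum_a A_{a,t}
    L(theta) = sum_t log sum_j A_{j,t}

M-step: weighted-frequency updates of both parameter blocks using the
posteriors ``B``.  If the argmax state sequence is unchanged over 3
consecutive iterations, the parameters are randomly re-initialized instead
of performing the M-step; the state sequence with the best likelihood seen
across all iterations (restarts included) is returned.

Two rounds are run per cluster: round 1 without parents, then a pairwise G²
search for up to 3 potential parents of the estimated sequence, and, if any
are found, round 2 conditioning on their configuration.  The final sequence
is suffix-shifted so that the hidden cause temporally precedes every cluster
member, and is then appendable to the data as an extra gene row per series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .citest import g2_test
from .timeseries import MISSING, TimeSeriesSet

__all__ = [
    "EMProblem",
    "EMState",
    "EMResult",
    "e_step",
    "m_step",
    "run_em",
    "find_potential_parents",
    "estimate_hidden",
]

#: floor applied to theta entries before the E-step product (avoids
#: zero-likelihood lock-in from degenerate parameter rows)
THETA_FLOOR = 1e-12


@dataclass
class EMProblem:
    """Aligned data for one cluster's hidden-cause estimation.

    ``X`` is (n_rows, n_members) with :data:`MISSING` where a member has no
    observation; ``Q`` (optional) holds a parent-configuration index per row,
    with index ``n_q - 1`` reserved for rows where some parent value is
    unavailable.  ``block_rows`` records the per-series row counts so the
    estimate can be split back.
    """

    X: np.ndarray
    n_states_hidden: int
    n_states_obs: int
    Q: np.ndarray | None = None
    n_q: int = 1
    block_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape[1] < 2:
            raise ValueError("a cluster must have at least two members")
        if not self.block_rows:
            self.block_rows = [self.X.shape[0]]


@dataclass
class EMState:
    theta_h: np.ndarray  # (n_q, n_s) rows P(h | Q=q)
    theta_g: np.ndarray  # (n_members, n_s, n_states_obs) rows P(g_i = x | h=j)
    posteriors: np.ndarray | None = None  # B, (n_rows, n_s)
    log_likelihood: float = -np.inf
    h: np.ndarray | None = None


@dataclass
class EMResult:
    h: np.ndarray
    theta_h: np.ndarray
    theta_g: np.ndarray
    log_likelihood: float
    ll_trace: list[float]

    def blocks(self, problem: EMProblem) -> list[np.ndarray]:
        out, start = [], 0
        for n in problem.block_rows:
            out.append(self.h[start: start + n])
            start += n
        return out


def _random_theta(problem: EMProblem, rng: np.random.Generator) -> EMState:
    n_s, n_o = problem.n_states_hidden, problem.n_states_obs
    th = rng.dirichlet(np.ones(n_s), size=problem.n_q)
    tg = rng.dirichlet(np.ones(n_o), size=(problem.X.shape[1], n_s))
    return EMState(theta_h=th, theta_g=tg)


def e_step(state: EMState, problem: EMProblem) -> EMState:
    """Compute posteriors B, the log-likelihood, and the argmax sequence."""
    th = np.clip(state.theta_h, THETA_FLOOR, None)
    tg = np.clip(state.theta_g, THETA_FLOOR, None)
    q = problem.Q if problem.Q is not None else np.zeros(problem.X.shape[0], dtype=np.int64)
    A = th[q].copy()  # (n_rows, n_s)
    for i in range(problem.X.shape[1]):
        obs = problem.X[:, i]
        m = obs != MISSING
        A[m] *= tg[i][:, obs[m]].T
    tot = A.sum(axis=1)
    ll = float(np.sum(np.log(tot)))
    B = A / tot[:, None]
    h = np.argmax(B, axis=1)
    return EMState(
        theta_h=state.theta_h,
        theta_g=state.theta_g,
        posteriors=B,
        log_likelihood=ll,
        h=h,
    )


def m_step(state: EMState, problem: EMProblem) -> EMState:
    """Weighted-frequency parameter updates from the posteriors."""
    B = state.posteriors
    if B is None:
        raise ValueError("m_step requires posteriors from e_step")
    n_s, n_o = problem.n_states_hidden, problem.n_states_obs
    q = problem.Q if problem.Q is not None else np.zeros(problem.X.shape[0], dtype=np.int64)
    th = np.zeros((problem.n_q, n_s))
    np.add.at(th, q, B)
    tots = th.sum(axis=1, keepdims=True)
    th = np.where(tots > 0, th / np.where(tots > 0, tots, 1.0), 1.0 / n_s)
    tg = np.zeros((problem.X.shape[1], n_s, n_o))
    for i in range(problem.X.shape[1]):
        obs = problem.X[:, i]
        m = obs != MISSING
        np.add.at(tg[i].T, obs[m], B[m])
        denom = tg[i].sum(axis=1, keepdims=True)
        tg[i] = np.where(denom > 0, tg[i] / np.where(denom > 0, denom, 1.0), 1.0 / n_o)
    return EMState(theta_h=th, theta_g=tg)


#: relative log-likelihood plateau tolerance used by the stall detector
STALL_RTOL = 1e-6


def run_em(
    problem: EMProblem,
    iters: int = 100,
    rng: np.random.Generator | None = None,
) -> EMResult:
    """Random init, then ``iters`` E/M cycles with stall-triggered restarts;
    the argmax sequence of the best-likelihood iteration is returned.

    A run is declared stalled — and the parameters randomly re-initialized
    instead of performing the M-step — when the argmax state sequence is
    unchanged over 3 consecutive iterations *and* the log-likelihood has
    plateaued over those iterations.  The states alone stabilize well before
    the likelihood converges, so without the plateau condition a restart
    would record an unconverged likelihood and bias the best-run selection.
    """
    rng = rng or np.random.default_rng()
    state = _random_theta(problem, rng)
    best: EMState | None = None
    trace: list[float] = []
    recent: list[np.ndarray] = []
    for _ in range(max(iters, 0)):
        state = e_step(state, problem)
        trace.append(state.log_likelihood)
        if best is None or state.log_likelihood > best.log_likelihood:
            best = state
        recent.append(state.h)
        stalled = (
            len(recent) >= 3
            and all(np.array_equal(recent[-1], r) for r in recent[-3:-1])
            and abs(trace[-1] - trace[-3]) <= STALL_RTOL * abs(trace[-1])
        )
        if stalled:
            state = _random_theta(problem, rng)
            recent.clear()
        else:
            state = m_step(state, problem)
    if best is None:  # iters == 0: report the initial parameters' E-step
        best = e_step(state, problem)
        trace.append(best.log_likelihood)
    return EMResult(
        h=best.h,
        theta_h=best.theta_h,
        theta_g=best.theta_g,
        log_likelihood=best.log_likelihood,
        ll_trace=trace,
    )


# ---------------------------------------------------------------------------
# potential parents and the full per-cluster estimation
# ---------------------------------------------------------------------------

def _aligned_pairs(
    h_blocks: list[np.ndarray],
    lo: int,
    data: TimeSeriesSet,
    gene: int,
    shift: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair h at reference time t with ``gene`` at time ``t - shift``."""
    hs, xs = [], []
    for k, hb in enumerate(h_blocks):
        T = data.series[k].shape[1]
        t0 = max(lo, shift)
        t1 = min(lo + len(hb), T + shift)
        if t1 <= t0:
            continue
        hs.append(hb[t0 - lo: t1 - lo])
        xs.append(data.series[k][gene, t0 - shift: t1 - shift])
    if not hs:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    return np.concatenate(hs), np.concatenate(xs)


def find_potential_parents(
    h_blocks: list[np.ndarray],
    lo: int,
    data: TimeSeriesSet,
    d: int,
    score_min: float = 2.0,
    max_parents: int = 3,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> list[tuple[int, int, float]]:
    """Search observed genes x shifts ``1..2d`` for likely parents of the
    estimated hidden sequence; keep at most the 3 best with score >= 2.

    The search covers all observed genes except ``exclude`` — the cluster's
    own members: each member is a child of the cause by construction, and its
    association with the estimate (which was computed *from* it) would
    otherwise masquerade as a parent signal whenever the member leads the
    alignment clock.  Returns ``(gene, shift, score)`` triples sorted by
    descending score.
    """
    hits: list[tuple[float, int, int]] = []
    # a true parent acts on the hidden node at shift (its delay into the
    # hidden cause) + (the cause's lag behind the reference clock), so the
    # search spans 1..2d rather than 1..d
    for g in range(data.n_genes):
        if g in exclude:
            continue
        for s in range(1, 2 * d + 1):
            hv, xv = _aligned_pairs(h_blocks, lo, data, g, s)
            if hv.size == 0:
                continue
            res = g2_test(xv, hv)
            if res.score >= score_min:
                hits.append((res.score, g, s))
    hits.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(g, s, sc) for sc, g, s in hits[:max_parents]]


def _build_problem(
    members: list[tuple[int, int]],
    data: TimeSeriesSet,
    n_states_hidden: int,
    parents: list[tuple[int, int, float]] | None = None,
) -> tuple[EMProblem, int]:
    """Aligned EM inputs for cluster members given as (gene, tau) with tau the
    clustering shift (positive = member lags the center).  Returns the problem
    and the reference-clock offset ``lo`` of alignment row 0."""
    specs = [(g, -tau) for g, tau in members]
    lo = min(s for _, s in specs)
    blocks = data.expanded_blocks(specs)
    X = np.concatenate(blocks, axis=0)
    Q = None
    n_q = 1
    if parents:
        qcols = []
        for k, blk in enumerate(blocks):
            T = data.series[k].shape[1]
            n_rows = blk.shape[0]
            t = np.arange(n_rows) + lo
            cols = np.full((n_rows, len(parents)), MISSING, dtype=np.int64)
            for m, (g, s, _) in enumerate(parents):
                src = t - s
                ok = (src >= 0) & (src < T)
                cols[ok, m] = data.series[k][g, src[ok]]
            qcols.append(cols)
        qall = np.concatenate(qcols, axis=0)
        n_o = data.n_states
        n_cfg = n_o ** len(parents)
        strides = n_o ** np.arange(len(parents) - 1, -1, -1)
        miss = (qall == MISSING).any(axis=1)
        Q = np.where(miss, n_cfg, np.clip(qall, 0, None) @ strides).astype(np.int64)
        n_q = n_cfg + 1  # last index pools rows with an unobserved parent value
    problem = EMProblem(
        X=X,
        n_states_hidden=n_states_hidden,
        n_states_obs=data.n_states,
        Q=Q,
        n_q=n_q,
        block_rows=[b.shape[0] for b in blocks],
    )
    return problem, lo


def estimate_hidden(
    members: list[tuple[int, int]],
    data: TimeSeriesSet,
    d: int = 4,
    em_iters: int = 100,
    n_states_hidden: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Two-round EM estimation for one cluster.

    ``members`` are ``(gene, tau)`` pairs (tau relative to the cluster
    center).  Returns per-series hidden rows aligned to the original series
    (each of length T_k, suffix-shifted so the hidden cause precedes every
    member, last entry state 0) plus a diagnostics dict.
    """
    if len(members) < 2:
        raise ValueError("hidden-cause estimation needs a cluster of size >= 2")
    rng = rng or np.random.default_rng()
    n_sh = n_states_hidden if n_states_hidden is not None else data.n_states
    problem, lo = _build_problem(members, data, n_sh)
    r1 = run_em(problem, iters=em_iters, rng=rng)
    h_blocks = r1.blocks(problem)
    parents = find_potential_parents(
        h_blocks, lo, data, d, exclude={g for g, _ in members}
    )
    result = r1
    if parents:
        problem2, lo2 = _build_problem(members, data, n_sh, parents=parents)
        result = run_em(problem2, iters=em_iters, rng=rng)
        h_blocks = result.blocks(problem2)
        lo = lo2
    # suffix shift: h'(t) = h(t + off), indexing the aligned estimate's rows
    # (row 0 sits at the latest member's lag, so h' precedes every member);
    # positions past the estimate's end and the last entry are state 0
    off = max(max(tau for _, tau in members), d) + 1
    rows: list[np.ndarray] = []
    for k, hb in enumerate(h_blocks):
        T = data.series[k].shape[1]
        row = np.zeros(T, dtype=np.int64)
        for t in range(T - 1):
            r = t + off
            if 0 <= r < len(hb):
                row[t] = hb[r]
        rows.append(row)
    info = {
        "parents": parents,
        "round1_ll": r1.log_likelihood,
        "final_ll": result.log_likelihood,
        "offset": off,
    }
    return rows, info
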
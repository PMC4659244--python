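"""G² (likelihood-ratio) independence tests on delay-shifted discrete series.

These are the scoring primitives behind the two-stage structure learner, the
candidate clustering, and the hidden-cause parent search.  A test's *score* is
``-log10(p-value)``, so the default structure-learning threshold of 2
corresponds to ``p = 0.01``.

Conventions for sparse tables (standard G-test practice): empty cells
contribute 0 to G²; rows/columns with a zero margin inside a conditioning
stratum reduce the degrees of freedom; strata with no observations are
skipped.  When everything collapses (fewer than two distinct values in either
variable) the test carries no evidence and returns ``p = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .timeseries import MISSING, TimeSeriesSet

__all__ = ["TestResult", "g2_test", "pair_delay_score", "series_similarity"]

# Smallest representable p-value; keeps score = -log10(p) finite.
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class TestResult:
    g2: float
    dof: int
    p_value: float
    score: float


def _no_evidence() -> TestResult:
    return TestResult(g2=0.0, dof=1, p_value=1.0, score=0.0)


def g2_test(
    x: np.ndarray,
    y: np.ndarray,
    cond: list[np.ndarray] | None = None,
) -> TestResult:
    """G² test of independence of ``x`` and ``y``, optionally within strata
    of the conditioning variables ``cond``.

    Rows where any variable carries the missing-marker are dropped pairwise.
    ``G² = 2 sum O ln(O/E)`` per stratum with expected counts from the
    stratum's margins; ``dof = sum (r_s - 1)(c_s - 1)`` over non-empty strata
    counting only rows/columns with a non-zero margin.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    cond = [np.asarray(c, dtype=np.int64) for c in (cond or [])]
    keep = (x != MISSING) & (y != MISSING)
    for c in cond:
        keep &= c != MISSING
    x, y = x[keep], y[keep]
    cond = [c[keep] for c in cond]
    if x.size == 0:
        return _no_evidence()

    # Compact the observed values of x and y to 0..r-1 / 0..c-1.
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    r, c = len(xv), len(yv)
    if r < 2 or c < 2:
        return _no_evidence()

    # Encode the conditioning configuration into a single stratum index.
    if cond:
        strat = np.zeros(x.size, dtype=np.int64)
        for col in cond:
            _, ci = np.unique(col, return_inverse=True)
            strat = strat * (ci.max() + 1) + ci
        _, strat = np.unique(strat, return_inverse=True)
        n_strat = strat.max() + 1
    else:
        strat = np.zeros(x.size, dtype=np.int64)
        n_strat = 1

    # counts[s, i, j] via one bincount over the combined index
    combined = (strat * r + xi) * c + yi
    counts = np.bincount(combined, minlength=n_strat * r * c).reshape(n_strat, r, c)

    totals = counts.sum(axis=(1, 2))
    row_m = counts.sum(axis=2)  # (n_strat, r)
    col_m = counts.sum(axis=1)  # (n_strat, c)
    g2 = 0.0
    dof = 0
    for s in range(n_strat):
        tot = totals[s]
        if tot == 0:
            continue
        E = np.outer(row_m[s], col_m[s]) / tot
        O = counts[s]
        nz = O > 0
        g2 += 2.0 * float(np.sum(O[nz] * np.log(O[nz] / E[nz])))
        rs = int(np.count_nonzero(row_m[s]))
        cs = int(np.count_nonzero(col_m[s]))
        dof += max(rs - 1, 0) * max(cs - 1, 0)
    if dof <= 0:
        return _no_evidence()
    p = float(chi2.sf(g2, dof))
    p = min(max(p, _P_FLOOR), 1.0)
    return TestResult(g2=float(g2), dof=dof, p_value=p, score=float(-np.log10(p)))


def pair_delay_score(data: TimeSeriesSet, i: int, j: int, tau: int) -> TestResult:
    """Score the delayed dependence of target ``j`` at ``t`` on gene ``i`` at
    ``t - tau`` (``tau >= 1``)."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    M = data.shifted_columns([(i, tau), (j, 0)])
    return g2_test(M[:, 0], M[:, 1])


def series_similarity(
    data: TimeSeriesSet,
    x: int,
    y: int,
    d: int,
) -> tuple[float, int]:
    """Best G² score of gene ``y`` shifted against gene ``x`` over shifts
    ``-d..d``, and the maximizing shift.

    A positive shift means ``y`` lags ``x``: ``x(t - shift)`` is paired with
    ``y(t)``.  Ties favour the smallest ``|shift|``, then the negative one.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    best_score, best_shift = -np.inf, 0
    for shift in sorted(range(-d, d + 1), key=lambda s: (abs(s), s)):
        try:
            M = data.shifted_columns([(x, shift), (y, 0)])
        except ValueError:
            continue  # no overlap at this shift
        res = g2_test(M[:, 0], M[:, 1])
        if res.score > best_score:
            best_score, best_shift = res.score, shift
    if best_score == -np.inf:
        raise ValueError("no shift produced any overlap")
    return float(best_score), int(best_shift)
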
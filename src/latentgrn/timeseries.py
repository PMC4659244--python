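"""Containers and alignment primitives for discrete expression time series.

A :class:`TimeSeriesSet` holds ``K`` series (genes x T_k integer matrices,
possibly ragged in length) sharing one state coding.  Two alignment operations
support delayed tests and hidden-cause estimation:

* :func:`TimeSeriesSet.shifted_columns` — delay each requested gene by its
  shift and keep, per series, only the fully-overlapping time points,
  concatenated across series (used by the G² tests).
* :func:`TimeSeriesSet.expanded_alignment` — pad to the union of the shifted
  time ranges instead, marking absent cells with :data:`MISSING` (used by the
  EM, which can use partially observed time points).

Sign convention, used consistently by the tests, clustering and parent
search: for a spec ``(gene, s)`` the aligned column at reference time ``t``
holds ``x_gene(t - s)``.  A positive shift therefore pushes the gene into the
past relative to the zero-shift reference — exactly the semantics of a
regulator acting with delay ``s`` on a target at shift 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for "no observation at this aligned time point"; never a valid state.
MISSING: int = -1

__all__ = ["TimeSeriesSet", "MISSING", "quantile_discretize"]


@dataclass
class TimeSeriesSet:
    """K discrete series with a consistent state coding."""

    series: list[np.ndarray]
    n_states: int
    gene_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.series = [np.asarray(s, dtype=np.int64) for s in self.series]
        if not self.series:
            raise ValueError("need at least one series")
        genes = {s.shape[0] for s in self.series}
        if len(genes) != 1:
            raise ValueError(f"series disagree on gene count: {sorted(genes)}")
        for s in self.series:
            if s.size and (s.min() < 0 or s.max() >= self.n_states):
                raise ValueError("states must be integers in [0, n_states)")

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[0]

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def lengths(self) -> list[int]:
        return [s.shape[1] for s in self.series]

    def with_rows(self, rows: list[list[np.ndarray]] | list[np.ndarray]) -> "TimeSeriesSet":
        """Return a copy with extra gene rows appended to every series.

        ``rows[r][k]`` is the r-th new row for series k (or a single list of
        per-series rows when appending one gene).
        """
        if rows and isinstance(rows[0], np.ndarray):
            rows = [rows]  # type: ignore[list-item]
        new_series = []
        for k, s in enumerate(self.series):
            extra = np.vstack([np.asarray(r[k], dtype=np.int64)[None, :] for r in rows])
            new_series.append(np.vstack([s, extra]))
        return TimeSeriesSet(series=new_series, n_states=self.n_states)

    # -- alignment ---------------------------------------------------------
    def shifted_columns(self, specs: list[tuple[int, int]]) -> np.ndarray:
        """Align the requested ``(gene, shift)`` columns on their overlap.

        Per series of length T the overlap has ``T - span`` rows with
        ``span = max(shifts) - min(shifts)``; the per-series overlaps are
        concatenated in series order.  Raises if no series has any overlap.
        """
        if not specs:
            raise ValueError("specs must be non-empty")
        shifts = [s for _, s in specs]
        lo, hi = min(shifts), max(shifts)
        blocks = []
        for s in self.series:
            T = s.shape[1]
            n = T - (hi - lo)
            if n <= 0:
                continue
            # reference times t = hi .. lo+T-1; column m holds x_g(t - shift_m)
            cols = [s[g, (hi - sh): (hi - sh) + n] for g, sh in specs]
            blocks.append(np.stack(cols, axis=1))
        if not blocks:
            raise ValueError("empty overlap in every series for the requested shifts")
        return np.concatenate(blocks, axis=0)

    def expanded_alignment(self, members: list[tuple[int, int]]) -> np.ndarray:
        """Align on the union of shifted ranges, padding with :data:`MISSING`.

        Per series of length T the aligned block has ``T + span`` rows; member
        ``(g, s)`` holds ``x_g(t - s)`` where defined and MISSING elsewhere
        (reference times run from ``lo`` to ``hi + T - 1``).
        """
        if not members:
            raise ValueError("members must be non-empty")
        shifts = [s for _, s in members]
        lo, hi = min(shifts), max(shifts)
        blocks = []
        for s in self.series:
            T = s.shape[1]
            n = T + (hi - lo)
            block = np.full((n, len(members)), MISSING, dtype=np.int64)
            for m, (g, sh) in enumerate(members):
                start = sh - lo
                block[start: start + T, m] = s[g, :]
            blocks.append(block)
        return np.concatenate(blocks, axis=0)

    def expanded_blocks(self, members: list[tuple[int, int]]) -> list[np.ndarray]:
        """Per-series expanded alignments (same layout as expanded_alignment)."""
        out = []
        for k in range(self.n_series):
            sub = TimeSeriesSet([self.series[k]], self.n_states)
            out.append(sub.expanded_alignment(members))
        return out


def quantile_discretize(matrix: np.ndarray, n_states: int) -> np.ndarray:
    """Per-gene equal-count binning of a real-valued genes x time matrix.

    Each gene's values are ranked and split into ``n_states`` equal-count bins
    (ties broken toward the lower bin, via a stable argsort of the values).
    A constant gene collapses to state 0 with a warning.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    matrix = np.asarray(matrix, dtype=float)
    out = np.zeros(matrix.shape, dtype=np.int64)
    T = matrix.shape[1]
    for g in range(matrix.shape[0]):
        row = matrix[g]
        if np.all(row == row[0]):
            logger.warning("gene %d is constant; assigning all time points state 0", g)
            continue
        order = np.argsort(row, kind="stable")
        ranks = np.empty(T, dtype=np.int64)
        ranks[order] = np.arange(T)
        out[g] = ranks * n_states // T
    return out
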
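"""Plain-text I/O: expression TSVs (genes as rows, time points as columns)
and edge lists (``src dst delay`` per line)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import TransitionNetwork
from .timeseries import TimeSeriesSet

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "write_network",
]


def write_expression_tsv(path: str | Path, matrix: np.ndarray, gene_names=None) -> None:
    matrix = np.asarray(matrix)
    names = gene_names or [f"g{i}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=names, columns=[f"t{j}" for j in range(matrix.shape[1])])
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index.astype(str))


def read_timeseries(paths: list[str | Path], n_states: int | None = None) -> TimeSeriesSet:
    series, names = [], None
    for p in paths:
        mat, gn = read_expression_tsv(p)
        series.append(mat.astype(np.int64))
        names = names or gn
    if n_states is None:
        n_states = int(max(s.max() for s in series)) + 1
    return TimeSeriesSet(series=series, n_states=n_states, gene_names=names)


def write_timeseries(ts: TimeSeriesSet, outdir: str | Path, prefix: str = "series") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, s in enumerate(ts.series):
        p = outdir / f"{prefix}_{k}.tsv"
        write_expression_tsv(p, s, ts.gene_names)
        paths.append(p)
    return paths


def write_network(net: TransitionNetwork, path: str | Path, cpts: bool = False) -> None:
    Path(path).write_text(net.to_edgelist())
    if cpts and net.cpts:
        Path(str(path) + ".cpt").write_text(net.cpts_to_text())


def read_network(
    path: str | Path, n_obs: int, n_states: int = 3, max_delay: int = 4
) -> TransitionNetwork:
    """Edge-list file; ids >= n_obs are treated as hidden by convention."""
    text = Path(path).read_text()
    net = TransitionNetwork.from_edgelist(text, n_obs=n_obs, n_states=n_states, max_delay=max_delay)
    hidden = {i for e in net.edges for i in (e.src, e.dst) if i >= n_obs}
    net.hidden_ids = hidden
    cpt_path = Path(str(path) + ".cpt")
    if cpt_path.exists():
        net.cpts = TransitionNetwork.cpts_from_text(cpt_path.read_text())
    return net
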
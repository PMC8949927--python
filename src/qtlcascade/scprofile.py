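"""Single-cell cluster expression summaries for candidate genes.

Total-count normalization, dot-plot statistics (fraction of cells
expressing, mean normalized expression per cluster) and marker-based
labeling of the proliferating cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CANONICAL_CLUSTERS = (
    "Alpha",
    "Delta",
    "Gamma",
    "Beta1",
    "Beta2",
    "Beta3",
    "Beta4",
    "BetaP",
)

DEFAULT_TARGET_SUM = 10_000.0
PROLIFERATION_MARKER = "Mki67"


@dataclass
class CellMatrix:
    """Cells x genes raw counts with a cluster label per cell."""

    counts: pd.DataFrame
    clusters: pd.Series

    def __post_init__(self):
        self.counts = pd.DataFrame(self.counts)
        self.clusters = pd.Series(self.clusters)
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        if set(self.clusters.index) != set(self.counts.index):
            raise ValueError("every cell must carry a cluster label")
        self.clusters = self.clusters.loc[self.counts.index]

    @property
    def genes(self) -> list:
        return list(self.counts.columns)

    @property
    def n_cells(self) -> int:
        return len(self.counts)


def normalize(cells: CellMatrix, target_sum: float = DEFAULT_TARGET_SUM) -> pd.DataFrame:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts are dropped with a warning; an empty
    matrix is an error.
    """
    if cells.n_cells == 0:
        raise ValueError("empty cell matrix")
    totals = cells.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero counts dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = cells.counts.loc[~zero]
    scaled = kept.div(totals[~zero], axis=0) * target_sum
    return np.log1p(scaled)


def dotplot_stats(cells: CellMatrix, genes, clusters=None) -> pd.DataFrame:
    """Per (cluster, gene): fraction of cells with raw count > 0 and mean
    normalized expression.

    Fractions use raw counts; means use the normalized matrix from
    :func:`normalize`.  An empty cluster is reported with zeros and the
    ``empty`` flag set.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cells.counts.columns]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    if clusters is None:
        clusters = sorted(cells.clusters.unique())
    norm = normalize(cells)
    labels = cells.clusters
    rows = []
    for cl in clusters:
        cell_ids = labels.index[labels == cl]
        norm_ids = norm.index.intersection(cell_ids)
        for g in genes:
            if len(cell_ids) == 0:
                rows.append(
                    {"cluster": cl, "gene": g, "fraction": 0.0, "mean": 0.0,
                     "n_cells": 0, "empty": True}
                )
                continue
            raw = cells.counts.loc[cell_ids, g]
            mean = float(norm.loc[norm_ids, g].mean()) if len(norm_ids) else 0.0
            rows.append(
                {
                    "cluster": cl,
                    "gene": g,
                    "fraction": float((raw > 0).mean()),
                    "mean": mean,
                    "n_cells": int(len(cell_ids)),
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


def label_proliferating(stats: pd.DataFrame, marker: str = PROLIFERATION_MARKER) -> str:
    """Cluster with the maximal mean of ``marker``; alphabetical tie-break."""
    sub = stats[stats["gene"] == marker]
    if sub.empty:
        raise ValueError(f"marker {marker!r} not present in dot-plot table")
    best = sub["mean"].max()
    winners = sorted(sub.loc[sub["mean"] == best, "cluster"])
    if len(winners) > 1:
        warnings.warn(
            f"marker {marker} ties across clusters {winners}; "
            "alphabetical tie-break",
            RuntimeWarning,
            stacklevel=2,
        )
    return winners[0]


def top_cluster_per_gene(stats: pd.DataFrame) -> dict:
    """Gene -> cluster with maximal mean expression (alphabetical ties)."""
    out = {}
    for g, sub in stats.groupby("gene"):
        best = sub["mean"].max()
        out[g] = sorted(sub.loc[sub["mean"] == best, "cluster"])[0]
    return out
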
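"""Cross-strategy connectome similarity and hierarchical ordering.

The cohort-mean edge vector of each denoising strategy is correlated with
every other strategy's, and the resulting similarity matrix is reordered by
average-linkage agglomerative clustering on distance 1 - r so that blocks
of mutually similar strategies (e.g. with vs without global signal
regression) appear contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import InputError


@dataclass
class StrategySimilarity:
    matrix: np.ndarray  # strategies x strategies Pearson r
    strategies: list[str]
    ordering: list[int]  # leaf order from hierarchical clustering

    @property
    def ordered_strategies(self) -> list[str]:
        return [self.strategies[i] for i in self.ordering]

    def to_tsv(self, matrix_path: str | Path,
               order_path: str | Path | None = None) -> None:
        pd.DataFrame(self.matrix, index=self.strategies,
                     columns=self.strategies).to_csv(
            matrix_path, sep="\t", float_format="%.10g")
        if order_path is not None:
            pd.DataFrame({"strategy": self.ordered_strategies}).to_csv(
                order_path, sep="\t", index=False)


def similarity_matrix(mean_edges: dict[str, np.ndarray]) -> tuple[
        np.ndarray, list[str]]:
    """Pairwise Pearson r between strategies' mean edge vectors."""
    if len(mean_edges) < 2:
        raise InputError("need >= 2 strategies")
    names = list(mean_edges)
    lengths = {np.asarray(v).size for v in mean_edges.values()}
    if len(lengths) != 1:
        raise InputError("edge vectors differ in length across strategies")
    stacked = np.vstack([np.asarray(mean_edges[n], dtype=float)
                         for n in names])
    if not np.isfinite(stacked).all():
        # drop edges missing for any strategy so every pair uses the
        # same support
        keep = np.isfinite(stacked).all(axis=0)
        stacked = stacked[:, keep]
    r = np.corrcoef(stacked)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, names


def hierarchical_order(matrix: np.ndarray) -> list[int]:
    """Average-linkage leaf order on distance 1 - r (lower index first on
    ties; scipy's deterministic ordering)."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 1:
        return [0]
    dist = 1.0 - matrix
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return [int(i) for i in leaves_list(Z)]


def strategy_similarity(
    mean_edges: dict[str, np.ndarray]
) -> StrategySimilarity:
    """Similarity matrix across strategies plus its clustered ordering."""
    r, names = similarity_matrix(mean_edges)
    ordering = hierarchical_order(r)
    return StrategySimilarity(r, names, ordering)
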
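"""Hierarchical clustering of activity/expression profiles.

Workflow of the classic Cluster 3.0 heatmap: rows (SNP alleles or genes) are
Z-scored, similarity is the *uncentered* Pearson correlation
``sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` (cosine similarity without mean
removal), distance is ``1 - similarity``, and agglomeration uses average
linkage by default.  Output is an ordered matrix plus Newick dendrograms so
external tree viewers can render them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize every row to mean 0, SD 1 (sample SD, ddof=1).

    Constant rows have no scale and are dropped with a warning.
    """
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant row(s): "
            f"{matrix.index[constant].tolist()[:5]}...",
            stacklevel=2,
        )
    kept = matrix.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def uncentered_pearson(x, y) -> float:
    """Uncentered Pearson similarity in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float((x * y).sum() / (nx * ny))


def _similarity_matrix(data: np.ndarray) -> np.ndarray:
    norms = np.sqrt((data * data).sum(axis=1))
    if (norms == 0).any():
        raise ValueError("zero-norm row encountered")
    unit = data / norms[:, None]
    s = unit @ unit.T
    return np.clip(s, -1.0, 1.0)


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray = field(repr=False)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels for the top k-group split."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster(
    matrix: pd.DataFrame, axis: str = "rows", linkage: str = "average"
) -> ClusterResult:
    """Agglomerative clustering on 1 - uncentered Pearson distances.

    ``axis`` is "rows" or "columns"; scipy's deterministic agglomeration
    order (lowest-index pair first on ties) is kept as-is.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items on the clustered axis")
    data = matrix.to_numpy(dtype=float)
    dist = 1.0 - _similarity_matrix(data)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult([str(l) for l in matrix.index], Z)


def cluster_profile(
    matrix: pd.DataFrame,
    axis: str = "both",
    linkage: str = "average",
    zscore: bool = True,
) -> tuple[pd.DataFrame, dict[str, ClusterResult]]:
    """Z-score rows, cluster the requested axes, return the reordered matrix."""
    m = zscore_rows(matrix) if zscore else matrix.copy()
    trees: dict[str, ClusterResult] = {}
    if axis in ("rows", "both"):
        trees["rows"] = hcluster(m, "rows", linkage)
        m = m.loc[trees["rows"].leaf_order]
    if axis in ("columns", "both"):
        trees["columns"] = hcluster(m, "columns", linkage)
        m = m[trees["columns"].leaf_order]
    if not trees:
        raise ValueError("axis must be 'rows', 'columns' or 'both'")
    return m, trees
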
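"""Sample-level structure summaries of the percent-methylation matrix:
hierarchical clustering (correlation distance, Ward linkage) and PCA.

Both operate on the tiles × samples percent matrix produced by
:func:`percent_matrix`; the coverage filter guarantees there are no missing
entries. Row (tile) order never affects the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tiling import TileMatrix


def percent_matrix(tm: TileMatrix) -> pd.DataFrame:
    """Tiles × samples matrix of 100·n_meth/n_total.

    Requires every cell to have reads (run the coverage filter first).
    """
    if (tm.total <= 0).any():
        bad = int((tm.total <= 0).sum())
        raise ValueError(
            f"{bad} tile/sample cells have zero coverage; apply filter_by_coverage first"
        )
    index = [f"{c}:{s}-{e}" for c, s, e in tm.tile_ids()]
    return pd.DataFrame(100.0 * tm.meth / tm.total, index=index, columns=tm.samples)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list  # sample ids, input order (leaf ids index into this)
    leaf_order: list  # sample ids in dendrogram left-to-right order
    distance: pd.DataFrame  # the 1 − correlation matrix used

    def cut(self, k: int) -> dict:
        """Partition samples into k flat clusters; returns sample -> cluster id."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, assignment.tolist()))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def build(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return build(tree, tree.dist) + ";"


def cluster_samples(matrix: pd.DataFrame, correlation: str = "pearson") -> ClusterResult:
    """Hierarchical clustering of samples with distance 1 − correlation and
    Ward's minimum-variance agglomeration.

    ``correlation`` is "pearson" (default) or "spearman". Ward linkage is
    applied to the correlation distance directly — the convention of
    methylKit's clusterSamples — although Ward's derivation assumes squared
    Euclidean distances.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 samples to cluster")
    stds = matrix.std(axis=0, ddof=0)
    zero_var = stds[stds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance sample column(s) {zero_var}: correlation undefined")
    corr = matrix.corr(method=correlation)
    dist = 1.0 - corr
    condensed = squareform(dist.to_numpy(), checks=False)
    condensed = np.maximum(condensed, 0.0)
    Z = hierarchy.linkage(condensed, method="ward")
    leaves = hierarchy.leaves_list(Z)
    labels = list(matrix.columns)
    return ClusterResult(
        linkage=Z,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
        distance=dist,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: np.ndarray  # components × tiles
    explained_variance_ratio: np.ndarray

    def component(self, i: int) -> pd.Series:
        return self.scores.iloc[:, i]


def pca_samples(matrix: pd.DataFrame, n_components: int = 3, scale: bool = False) -> PCAResult:
    """PCA of samples over tiles (tiles centred, unscaled by default).

    Sample scores on the top ``n_components`` components are returned with
    explained-variance fractions in decreasing order. For reproducibility the
    sign of each component is fixed so its largest-magnitude tile loading is
    positive.
    """
    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValueError("need >=2 samples for PCA")
    if not 1 <= n_components <= n_samples - 1:
        raise ValueError(
            f"n_components must be in [1, n_samples-1] = [1, {n_samples - 1}], got {n_components}"
        )
    X = matrix.to_numpy(dtype=float).T  # samples × tiles
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    evr = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(min(n_components, len(S))):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        loadings=Vt[:n_components],
        explained_variance_ratio=evr[:n_components],
    )
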
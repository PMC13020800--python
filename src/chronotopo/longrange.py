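"""Long-range relationships between regional duration preferences.

Across subjects, regions whose median duration preferences rise and fall
together are functionally related even when anatomically distant.  The
group-level Kendall tau-b correlation matrix over a subject x region table
of median preferences captures these relationships; converting the matrix
rows to Euclidean distances and agglomerating with complete linkage yields a
dendrogram whose clusters group regions with co-varying preferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class CorrMatrix:
    """Symmetric Kendall tau-b matrix with unit diagonal."""

    labels: list
    tau: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.tau.to_numpy(dtype=float)
        if t.shape[0] != t.shape[1]:
            raise ValueError("tau matrix must be square")
        if not np.allclose(t, t.T, equal_nan=True):
            raise ValueError("tau matrix must be symmetric")


@dataclass
class Dendrogram:
    """Complete-linkage merge history over labelled items."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list:
        return [self.labels[i] for i in leaves_list(self.merges)]

    def cut(self, n_clusters: int) -> dict:
        """Label -> cluster id (1-based) at a flat cut into n clusters."""
        assign = fcluster(self.merges, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        trees = {i: str(self.labels[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - node_height[a]
            lb = h - node_height[b]
            idx = n + step
            trees[idx] = f"({trees[a]}:{la:g},{trees[b]}:{lb:g})"
            node_height[idx] = h
        return trees[2 * n - 2] + ";"


def preference_corr_matrix(median_mu: pd.DataFrame) -> CorrMatrix:
    """Pairwise Kendall tau-b over subjects for every region pair.

    ``median_mu`` is a subject x region table.  Regions whose medians are
    identical across all subjects produce undefined (NaN) off-diagonal
    entries; the diagonal is 1 by definition.
    """
    if median_mu.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if median_mu.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    tau = median_mu.corr(method="kendall")
    np.fill_diagonal(tau.values, 1.0)
    constant = median_mu.nunique(axis=0) <= 1
    for region in median_mu.columns[constant]:
        tau.loc[region, :] = np.nan
        tau.loc[:, region] = np.nan
        tau.loc[region, region] = 1.0
    return CorrMatrix(list(median_mu.columns), tau)


def corr_to_distance(m: CorrMatrix, method: str = "row_euclidean") -> pd.DataFrame:
    """Convert a correlation matrix into a distance matrix.

    ``row_euclidean`` (default) takes Euclidean distances between the rows of
    the full square matrix, treating it as an observations x variables table
    — the behaviour of applying a stock distance function directly to the
    matrix.  ``one_minus`` uses 1 - tau instead.
    """
    t = m.tau.to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("correlation matrix has missing entries")
    if method == "row_euclidean":
        d = squareform(pdist(t))
    elif method == "one_minus":
        d = 1.0 - t
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError("method must be 'row_euclidean' or 'one_minus'")
    return pd.DataFrame(d, index=m.labels, columns=m.labels)


def hierarchical_cluster(d: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a square distance matrix.

    Complete linkage by default: the distance between clusters is the
    maximum pairwise distance between their members, giving non-decreasing
    merge heights (an ultrametric).
    """
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 items")
    merges = linkage(squareform(dm, checks=False), method=method)
    return Dendrogram(merges, list(d.index))
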
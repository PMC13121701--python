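"""Sample-structure analyses: z-scoring, hierarchical clustering, Spearman
correlation, PCA, and a cluster-purity statistic.

These answer the study's central question directly: when the 12 samples are
clustered or embedded, do they group by culture medium or by donor?  The
purity statistic makes the visual impression quantitative: cut the
dendrogram into k clusters and score the fraction of samples whose
cluster's majority label matches their own.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

__all__ = [
    "zscore_log",
    "Dendrogram",
    "cluster_samples",
    "spearman_matrix",
    "PCAResult",
    "pca",
    "grouping_purity",
]

log = logging.getLogger(__name__)


def zscore_log(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization of log2 intensities.

    Each row of the returned matrix has mean 0 and sample SD 1 (n-1
    denominator); rows constant on the log scale map to all-zero rows with
    a logged warning.  Non-positive intensities are a domain error.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("intensities must be strictly positive to take logs")
    lg = np.log2(vals)
    mu = lg.mean(axis=1, keepdims=True)
    sd = lg.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        log.warning("zscore_log: %d constant gene row(s) mapped to zero", int(constant.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((lg - mu) / sd, index=matrix.index, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Agglomeration of samples: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster ids (1..k) from the standard k-cluster cut."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def cluster_samples(data: pd.DataFrame, metric: str = "euclidean", method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the sample columns.

    Complete linkage on Euclidean distances by default: inter-cluster
    distance is the maximum pairwise sample distance.  scipy's linkage
    breaks ties deterministically by the order distances are stored, which
    with our fixed column order yields the smallest-index pair.
    """
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    x = data.to_numpy(dtype=float).T  # samples as observations
    z = hierarchy.linkage(pdist(x, metric=metric), method=method)
    return Dendrogram(linkage=z, labels=list(data.columns))


def spearman_matrix(matrix: pd.DataFrame, allow_constant: bool = False) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample columns (mid-ranks for ties).

    A constant column has undefined rank correlation; such entries are NaN
    and an error is raised unless ``allow_constant``.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 genes for rank correlation")
    vals = matrix.to_numpy(dtype=float)
    constant = (vals == vals[0]).all(axis=0)
    if constant.any() and not allow_constant:
        bad = list(matrix.columns[constant])
        raise ValueError(f"constant sample column(s) make Spearman r undefined: {bad}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns handled below
        if matrix.shape[1] == 2:
            r, _ = spearmanr(vals[:, 0], vals[:, 1])
            corr = np.array([[1.0, r], [r, 1.0]])
        else:
            corr, _ = spearmanr(vals)  # columns = variables
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    corr[np.ix_(constant, ~constant)] = np.nan
    corr[np.ix_(~constant, constant)] = np.nan
    corr[np.ix_(constant, constant)] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


@dataclass
class PCAResult:
    """Sample scores, gene loadings (importance = |loading|), and variance explained (%)."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    r2: pd.Series  # % of total variance per component

    def top_genes(self, component: str, k: int = 3) -> list[str]:
        """The k genes with the largest loading magnitude on a component."""
        return self.loadings[component].abs().sort_values(ascending=False).head(k).index.tolist()


def pca(z: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of samples in standardized gene space, via SVD of the centered data.

    Samples are observations, genes are features.  R^2 per component is the
    percentage of total variance; the sign convention makes each
    component's largest-magnitude gene loading positive.  ``n_components``
    exceeding the data rank is reduced with a warning.
    """
    if z.shape[0] == 0:
        raise ValueError("gene set is empty")
    x = z.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        log.warning("pca: n_components reduced from %d to rank %d", n_components, rank)
        n_components = rank
    comps = [f"PC{i + 1}" for i in range(n_components)]
    total_var = float((s**2).sum())
    scores = u[:, :n_components] * s[:n_components]
    load = vt[:n_components].T  # genes x components
    # sign convention: dominant loading positive
    for j in range(n_components):
        i_max = np.argmax(np.abs(load[:, j]))
        if load[i_max, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    r2 = 100.0 * (s[:n_components] ** 2) / total_var
    return PCAResult(
        scores=pd.DataFrame(scores, index=z.columns, columns=comps),
        loadings=pd.DataFrame(load, index=z.index, columns=comps),
        r2=pd.Series(r2, index=comps, name="r2_percent"),
    )


def grouping_purity(dendrogram: Dendrogram, labels: pd.Series, k: int) -> float:
    """Majority-label purity of the k-cluster cut of a sample dendrogram.

    labels maps sample id -> factor level.  Purity = (sum over clusters of
    the majority-label count) / n; 1.0 means clusters coincide with the
    factor's levels.
    """
    assign = dendrogram.cut(k)
    lab = labels.reindex(dendrogram.labels).to_numpy()
    n = len(lab)
    correct = 0
    for c in np.unique(assign):
        _, counts = np.unique(lab[assign == c], return_counts=True)
        correct += int(counts.max())
    return correct / n
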
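"""Unsupervised grouping of neurons by their intrinsic properties.

The population stage clusters Z-scored feature profiles with Pearson
correlation distance (1 - r) and average linkage; subcluster stages use
Euclidean distance with Ward linkage.  The number of clusters is chosen by
the maximum average silhouette width over k = 2..9; an average width below
0.25 flags random structure.  t-SNE and modified LLE embeddings are
available as validation views.

:class:`HierarchicalNeuronClustering` is a scikit-learn-style estimator;
the module-level functions are thin wrappers used by the CLI.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.manifold import TSNE, LocallyLinearEmbedding
from sklearn.metrics import silhouette_samples

__all__ = [
    "zscore",
    "hcluster",
    "cut",
    "silhouette_curve",
    "tsne_embed",
    "lle_embed",
    "dendrogram_to_newick",
    "HierarchicalNeuronClustering",
]

RANDOM_STRUCTURE_SI = 0.25
TSNE_PROFILES = {
    "all": {"perplexity": 25, "early_exaggeration": 1.0},
    "pn": {"perplexity": 8, "early_exaggeration": 7.0},
    "in": {"perplexity": 7, "early_exaggeration": 7.0},
}
LLE_NEIGHBORS = {"pn": 14, "in": 13}


def zscore(m: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise Z-scores (sample SD); constant columns become zeros with
    a warning; missing values are imputed as 0 (the column mean) after
    scaling."""
    x = np.asarray(m, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s) set to zero", stacklevel=2)
    sd_safe = np.where(const, 1.0, sd)
    z = (x - mean) / sd_safe
    z[:, const] = 0.0
    return np.nan_to_num(z, nan=0.0)


def _distances(z: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pearson":
        d = pdist(z, metric="correlation")  # 1 - r
    elif metric == "euclidean":
        d = pdist(z, metric="euclidean")
    else:
        raise ValueError(f"unknown metric '{metric}'")
    return np.clip(d, 0.0, None)


def hcluster(
    z: np.ndarray, metric: str = "pearson", linkage: str = "average"
) -> np.ndarray:
    """Agglomerative clustering; returns a SciPy linkage matrix.

    The population run pairs Pearson correlation distance with average
    linkage; subcluster runs pair Euclidean distance with Ward linkage.
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("NaNs remain after imputation")
    if linkage == "ward":
        if metric != "euclidean":
            raise ValueError("Ward linkage requires Euclidean distances")
        return hierarchy.linkage(z, method="ward")
    return hierarchy.linkage(_distances(z, metric), method=linkage)


def cut(link: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels (0-based) after cutting the k-1 highest merges."""
    n = link.shape[0] + 1
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    return hierarchy.fcluster(link, t=k, criterion="maxclust") - 1


def silhouette_curve(
    z: np.ndarray,
    link: np.ndarray,
    metric: str = "pearson",
    kmax: int = 9,
) -> dict:
    """Average silhouette width for k = 2..kmax cuts of the dendrogram.

    Widths are computed on the same distances used for clustering.  Returns
    ``{"k": ..., "width": ..., "per_cell": {k: widths}, "best_k": ...,
    "random_structure": ...}``; singleton clusters contribute width 0 and
    ties in the argmax go to the smallest k.
    """
    n = z.shape[0]
    dmat = squareform(_distances(np.asarray(z, float), metric))
    ks = [k for k in range(2, kmax + 1) if k <= n - 1]
    widths, per_cell = [], {}
    for k in ks:
        labels = cut(link, k)
        s = silhouette_samples(dmat, labels, metric="precomputed")
        # singleton clusters: silhouette width defined as 0
        _, counts = np.unique(labels, return_counts=True)
        for c in np.flatnonzero(counts == 1):
            s[labels == c] = 0.0
        per_cell[k] = s
        widths.append(float(np.mean(s)))
    widths_arr = np.asarray(widths)
    best_k = ks[int(np.argmax(widths_arr))]  # argmax takes the first (smallest k)
    return {
        "k": ks,
        "width": widths_arr,
        "per_cell": per_cell,
        "best_k": best_k,
        "random_structure": bool(np.max(widths_arr) < RANDOM_STRUCTURE_SI),
    }


def tsne_embed(
    z: np.ndarray, profile: str = "all", seed: int = 0, max_iter: int = 1000
) -> np.ndarray:
    """2-D t-SNE embedding with the profile-specific settings
    (learning rate 200, PCA initialization, Euclidean distances)."""
    cfg = TSNE_PROFILES[profile]
    n = np.asarray(z).shape[0]
    if n < 3 * cfg["perplexity"]:
        raise ValueError(
            f"n={n} too small for perplexity {cfg['perplexity']} (need >= 3x)"
        )
    ts = TSNE(
        n_components=2,
        perplexity=cfg["perplexity"],
        early_exaggeration=max(cfg["early_exaggeration"], 1.0),
        learning_rate=200.0,
        init="pca",
        max_iter=max_iter,
        random_state=seed,
        metric="euclidean",
    )
    return ts.fit_transform(np.asarray(z, float))


def lle_embed(z: np.ndarray, profile: str, seed: int = 0, max_iter: int = 100) -> np.ndarray:
    """2-D modified locally-linear embedding (neighbors: PN 14, IN 13)."""
    nn = LLE_NEIGHBORS[profile]
    z = np.asarray(z, float)
    if z.shape[0] <= nn:
        raise ValueError(f"n={z.shape[0]} too small for {nn} neighbors")
    lle = LocallyLinearEmbedding(
        n_neighbors=nn,
        n_components=2,
        method="modified",
        max_iter=max_iter,
        random_state=seed,
    )
    return lle.fit_transform(z)


def dendrogram_to_newick(link: np.ndarray, labels: list[str] | None = None) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)
    labels = labels or [str(i) for i in range(link.shape[0] + 1)]

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


class HierarchicalNeuronClustering(BaseEstimator, ClusterMixin):
    """Hierarchical clustering with silhouette-based model selection.

    Parameters
    ----------
    stage : {"population", "subcluster"}
        ``population`` uses Pearson correlation distance with average
        linkage; ``subcluster`` uses Euclidean distance with Ward linkage.
    kmax : int
        Largest number of clusters scanned by the silhouette analysis.
    k : int or None
        Fixed number of clusters; when None the silhouette optimum is used.

    Attributes
    ----------
    linkage_ : ndarray
        SciPy linkage matrix of the fitted dendrogram.
    labels_ : ndarray
        Cluster labels at ``best_k_``.
    best_k_ : int
    silhouette_ : dict
        Output of :func:`silhouette_curve`.
    random_structure_ : bool
        True when the best average silhouette width is below 0.25.
    """

    def __init__(self, stage: str = "population", kmax: int = 9, k: int | None = None):
        self.stage = stage
        self.kmax = kmax
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        z = zscore(X)
        metric, linkage = (
            ("pearson", "average") if self.stage == "population" else ("euclidean", "ward")
        )
        self.zscored_ = z
        self.metric_ = metric
        self.linkage_ = hcluster(z, metric=metric, linkage=linkage)
        self.silhouette_ = silhouette_curve(z, self.linkage_, metric=metric, kmax=self.kmax)
        self.best_k_ = self.k if self.k is not None else self.silhouette_["best_k"]
        self.labels_ = cut(self.linkage_, self.best_k_)
        self.random_structure_ = self.silhouette_["random_structure"]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
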
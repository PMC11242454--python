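"""Cluster cultivars into growth-performance groups and test their separation.

Cultivar-level growth traits (shoot biomass, leaf count, tuber weight and
number) are z-scored, clustered with k-means (k chosen by the within-sum-of-
squares elbow or mean silhouette) and, as a reproducibility check, with
Ward-variance hierarchical clustering (the ward.D2 convention on Euclidean
distances).  For k = 3 the clusters are ranked into high / medium / low
performance; group separation is tested with ANOSIM on Euclidean distances
between scaled trait vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from skbio import DistanceMatrix

from .stats import anosim

__all__ = [
    "GrowthClusters",
    "scale_traits",
    "select_k",
    "kmeans_cluster",
    "hierarchical_cluster",
    "rank_clusters",
    "trait_anosim",
]

PERFORMANCE_ORDER = ["high", "medium", "low"]


@dataclass
class GrowthClusters:
    labels: pd.Series  # cultivar -> label
    k: int
    method: str

    def __post_init__(self) -> None:
        if self.labels.nunique() != self.k:
            raise ValueError(
                f"k={self.k} but {self.labels.nunique()} distinct labels present"
            )


def scale_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1 with n−1 denominator)."""
    if traits.shape[0] < 2:
        raise ValueError("need at least 2 cultivars to scale")
    sd = traits.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"zero-variance trait column(s): {constant}")
    return (traits - traits.mean(axis=0)) / sd


def _wss(scaled: np.ndarray, k: int, seed: int, n_init: int = 10) -> float:
    if k == 1:
        return float(((scaled - scaled.mean(axis=0)) ** 2).sum())
    if k == scaled.shape[0]:
        return 0.0
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scaled)
    return float(km.inertia_)


def select_k(
    scaled: pd.DataFrame | np.ndarray,
    k_max: int = 10,
    criterion: str = "wss",
    seed: int = 0,
) -> int:
    """Choose the number of clusters.

    ``wss``: elbow of the total within-cluster sum of squares — the k in
    2..k_max−1 maximizing the curvature (second difference) of the WSS
    curve on the log scale.  The log scale makes the elbow scale-free:
    on the raw scale the k = 1 → 2 drop dominates whenever clusters are
    roughly collinear, regardless of the true number of groups.
    ``silhouette``: argmax of the mean silhouette over k = 2..k_max; a
    best silhouette below 0.25 triggers a "weak structure" warning.
    """
    X = np.asarray(scaled, dtype=float)
    n = X.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be < number of rows ({n})")
    if criterion == "wss":
        wss = np.array([_wss(X, k, seed) for k in range(1, k_max + 1)])
        log_wss = np.log(np.maximum(wss, 1e-12))
        second_diff = log_wss[:-2] - 2 * log_wss[1:-1] + log_wss[2:]  # k = 2..k_max-1
        return int(np.argmax(second_diff) + 2)
    if criterion == "silhouette":
        scores = {}
        for k in range(2, k_max + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            if len(np.unique(km.labels_)) < 2:
                continue
            scores[k] = silhouette_score(X, km.labels_)
        best = max(scores, key=scores.get)
        if scores[best] < 0.25:
            warnings.warn(
                f"weak structure: best mean silhouette {scores[best]:.3f} at k={best}",
                stacklevel=2,
            )
        return int(best)
    raise ValueError(f"unknown criterion {criterion!r}")


def kmeans_cluster(
    scaled: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25
) -> GrowthClusters:
    """k-means on scaled traits, best of ``n_init`` restarts by WSS."""
    if k > scaled.shape[0]:
        raise ValueError(f"k ({k}) exceeds number of cultivars ({scaled.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(
        np.asarray(scaled, dtype=float)
    )
    labels = pd.Series(km.labels_, index=scaled.index, name="cluster")
    return GrowthClusters(labels=labels, k=k, method="kmeans")


def hierarchical_cluster(scaled: pd.DataFrame, k: int) -> GrowthClusters:
    """Ward-variance agglomeration (ward.D2 on Euclidean distances), cut at k."""
    if k > scaled.shape[0]:
        raise ValueError(f"k ({k}) exceeds number of cultivars ({scaled.shape[0]})")
    Z = linkage(np.asarray(scaled, dtype=float), method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust") - 1
    labels = pd.Series(flat, index=scaled.index, name="cluster")
    return GrowthClusters(labels=labels, k=k, method="hierarchical")


def rank_clusters(
    clusters: GrowthClusters, traits: pd.DataFrame
) -> GrowthClusters:
    """Relabel clusters by performance: high / medium / low for k = 3.

    Clusters are ordered by descending mean of row-summed scaled traits;
    ties are broken by the cluster with the heavier mean tuber weight.
    For k ≠ 3 generic ordered labels ``rank_1`` (best) … are used.
    """
    scaled = scale_traits(traits)
    summed = scaled.sum(axis=1)
    order_keys = {}
    for c in clusters.labels.unique():
        members = clusters.labels.index[clusters.labels == c]
        tuber = (
            traits.loc[members, "tuber_weight"].mean()
            if "tuber_weight" in traits.columns
            else 0.0
        )
        order_keys[c] = (float(summed[members].mean()), float(tuber))
    ranked = sorted(order_keys, key=lambda c: order_keys[c], reverse=True)
    if clusters.k == 3:
        names = dict(zip(ranked, PERFORMANCE_ORDER))
    else:
        names = {c: f"rank_{i + 1}" for i, c in enumerate(ranked)}
    return GrowthClusters(
        labels=clusters.labels.map(names), k=clusters.k, method=clusters.method
    )


def trait_anosim(
    scaled: pd.DataFrame, labels: pd.Series, n_perm: int = 999, seed: int = 0
):
    """ANOSIM on Euclidean distances between scaled trait vectors."""
    dm = DistanceMatrix(squareform(pdist(np.asarray(scaled, dtype=float))), ids=list(scaled.index))
    return anosim(dm, labels.loc[scaled.index], n_perm=n_perm, seed=seed)
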
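"""Clustering of bottleneck representations and cluster-quality scoring.

k-means (Lloyd's algorithm with kmeans++ seeding and multiple restarts) runs
over the 100-dimensional bottleneck; the number of groups is selected over
k = 2..5 by the mean silhouette score.  For the centroid-managed losses the
final training centroids label the samples directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .losses import CentroidState, nearest_two_centroids


class ClusterSource(str, Enum):
    KMEANS_ON_BOTTLENECK = "kmeans_on_bottleneck"
    FINAL_TRAINING_CENTROIDS = "final_training_centroids"


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    silhouette: float
    source: ClusterSource

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not -1.0 <= self.silhouette <= 1.0:
            raise ValueError("silhouette must lie in [-1, 1]")

    @property
    def sizes(self) -> list[int]:
        return np.bincount(self.labels, minlength=self.k).tolist()


def silhouette(b: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over samples, Euclidean distance:
    s(i) = (b(i) - a(i)) / max{a(i), b(i)} with a(i) the mean within-cluster
    distance and b(i) the smallest mean distance to another cluster.
    Singleton clusters contribute s(i) = 0; the all-singletons case (every
    point its own cluster) is defined as 0.
    """
    b = np.asarray(b, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    if (counts == 1).all():
        return 0.0
    return float(np.mean(silhouette_samples(b, labels, metric="euclidean")))


def kmeans(b: np.ndarray, k: int, seed: int, n_restarts: int = 10) -> ClusterResult:
    """Full Lloyd's algorithm with kmeans++ initialisation and ``n_restarts``
    seeded restarts; deterministic given ``seed``."""
    b = np.asarray(b, dtype=float)
    n = b.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the sample count {n}")
    km = KMeans(n_clusters=k, init="k-means++", algorithm="lloyd",
                n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(b)
    score = silhouette(b, labels) if len(np.unique(labels)) > 1 else 0.0
    return ClusterResult(labels, k, score, ClusterSource.KMEANS_ON_BOTTLENECK)


def select_k(b: np.ndarray, k_range: tuple[int, int] = (2, 5), seed: int = 0) -> ClusterResult:
    """Run k-means for each k in ``k_range`` (inclusive) and return the
    clustering with the highest silhouette; ties resolve to the smallest k."""
    best: ClusterResult | None = None
    for k in range(k_range[0], k_range[1] + 1):
        if k > b.shape[0]:
            break
        res = kmeans(b, k, seed)
        if best is None or res.silhouette > best.silhouette:
            best = res
    assert best is not None
    return best


def labels_from_centroids(b: np.ndarray, cs: CentroidState) -> ClusterResult:
    """Nearest-centroid labels from the final training centroids (ties break
    to the lower centroid index).  An empty cluster is retained with a warning
    — no repair at evaluation time."""
    import logging

    b = np.asarray(b, dtype=float)
    mu_idx, _ = nearest_two_centroids(b, cs.centroids)
    occupied = np.unique(mu_idx)
    if occupied.size < cs.k:
        logging.getLogger(__name__).warning(
            "labels_from_centroids: %d of %d centroids own no samples",
            cs.k - occupied.size, cs.k)
    score = silhouette(b, mu_idx) if occupied.size > 1 else 0.0
    return ClusterResult(mu_idx, cs.k, score, ClusterSource.FINAL_TRAINING_CENTROIDS)
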
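"""Partition the embedded map into named clusters.

Hierarchical agglomerative clustering (Ward linkage on Euclidean distances
in the 2-D embedding) segments the map into compact, visually separable
regions. Clusters receive alphabetic names A, B, C, ... in order of
decreasing size, and each cluster's center is the centroid (coordinate
mean) of its members — the point candidate substrates are later ranked
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score as _sk_silhouette

__all__ = [
    "ClusterModel",
    "ClusterQuality",
    "cluster_map",
    "silhouette_score",
    "scan_cluster_numbers",
    "cluster_names",
]

DEFAULT_K = 15
DEFAULT_K_MIN = 10
DEFAULT_K_MAX = 25


def cluster_names(k: int) -> list[str]:
    """Alphabetic names A..Z, then AA, AB, ... for k clusters."""
    names = []
    for i in range(k):
        name = ""
        j = i
        while True:
            name = chr(ord("A") + j % 26) + name
            j = j // 26 - 1
            if j < 0:
                break
        names.append(name)
    return names


@dataclass(frozen=True)
class ClusterModel:
    """A k-way partition of the reference map with centers and names.

    ``names[labels[i]]`` is molecule i's cluster name; names are assigned
    in order of decreasing cluster size (ties broken by original label
    index) so cluster A is always the most populated region.
    """

    k: int
    labels: np.ndarray  # (n,) ints in [0, k)
    centers: np.ndarray  # (k, 2) centroid per cluster, row i = cluster with name names[i]
    names: tuple[str, ...]
    linkage: str

    def __post_init__(self):
        if len(self.names) != self.k or len(set(self.names)) != self.k:
            raise ValueError("need k unique cluster names")
        if self.centers.shape != (self.k, 2):
            raise ValueError("centers must be k x 2")
        if not np.isin(self.labels, np.arange(self.k)).all():
            raise ValueError("labels must lie in [0, k)")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass(frozen=True)
class ClusterQuality:
    """Silhouette score S in [-1, 1] for a k-cluster labeling."""

    S: float
    k: int

    def __post_init__(self):
        if not -1.0 <= self.S <= 1.0 + 1e-12:
            raise ValueError("silhouette out of [-1, 1]")


def cluster_map(coords: np.ndarray, k: int, linkage: str = "ward") -> ClusterModel:
    """Agglomerative clustering of 2-D coordinates into k named clusters.

    Deterministic: agglomerative clustering involves no randomness.
    Labels are re-indexed so that label 0 (= name "A") is the largest
    cluster; centers are recomputed as the coordinate means of the final
    labels.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    n = coords.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n (k={k}, n={n})")
    raw = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(coords)
    # relabel by decreasing size, stable on the original label for ties
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw]
    centers = np.vstack([coords[labels == i].mean(axis=0) for i in range(k)])
    return ClusterModel(
        k=k,
        labels=labels,
        centers=centers,
        names=tuple(cluster_names(k)),
        linkage=linkage,
    )


def silhouette_score(coords: np.ndarray, labels: np.ndarray) -> ClusterQuality:
    """Mean silhouette (b - a)/max(a, b) over all points.

    a = mean distance to the point's own cluster, b = smallest mean
    distance to another cluster; points in singleton clusters contribute 0.
    Requires at least two distinct labels and n >= 3.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.shape[0] < 3:
        raise ValueError("need n >= 3 points")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    s = float(_sk_silhouette(coords, labels, metric="euclidean"))
    return ClusterQuality(S=s, k=int(uniq.size))


def scan_cluster_numbers(
    coords: np.ndarray,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    linkage: str = "ward",
):
    """Silhouette score for every cluster count in [k_min, k_max].

    Returns a DataFrame with one (k, S) row per count, each equal to a
    standalone cluster_map + silhouette_score run.
    """
    import pandas as pd

    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    n = np.asarray(coords).shape[0]
    if k_max > n:
        raise ValueError(f"k_max ({k_max}) exceeds number of points ({n})")
    rows = []
    for k in range(k_min, k_max + 1):
        model = cluster_map(coords, k, linkage=linkage)
        rows.append({"k": k, "S": silhouette_score(coords, model.labels).S})
    return pd.DataFrame(rows)
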
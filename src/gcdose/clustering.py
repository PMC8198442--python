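"""Hierarchical and k-means clustering of expression profiles.

Hierarchical clustering wraps scipy's agglomerative linkage (Euclidean or
Pearson-correlation distance; average or complete linkage) and can export
the dendrogram as Newick.  K-means is Lloyd's algorithm with squared
Euclidean distance, repeated over many random initializations with the
best (minimum within-cluster sum of squares) run kept, and the number of
clusters selected by the Calinski-Harabasz criterion

    CH(k) = (B / (k - 1)) / (W / (n - k)),

where B and W are the between- and within-cluster dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "Dendrogram",
    "ClusterResult",
    "hierarchical_cluster",
    "kmeans_select",
    "calinski_harabasz",
]


@dataclass
class Dendrogram:
    """Agglomerative merge sequence with metric/linkage metadata."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: list[str]
    distance: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        parts = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            i, j = int(i), int(j)
            bi = h - heights[i]
            bj = h - heights[j]
            node = n + k
            parts[node] = f"({parts[i]}:{bi:g},{parts[j]}:{bj:g})"
            heights[node] = h
        return parts[n + len(self.merges) - 1] + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
    axis: str = "rows",
) -> Dendrogram:
    """Agglomerative clustering of rows (genes) or columns (samples)."""
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    X = matrix.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 items to cluster")
    if distance == "euclidean":
        dists = pdist(X, metric="euclidean")
    elif distance == "correlation":
        dists = pdist(X, metric="correlation")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if np.isnan(dists).any():
        raise ValueError("NaN distances (constant rows under correlation distance?)")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(Z, [str(i) for i in matrix.index], distance, linkage)


def _lloyd(
    X: np.ndarray, init_idx: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One run of Lloyd's k-means; returns labels, centers, WCSS, history.

    Ties in nearest-centroid assignment break to the lowest centroid index
    (argmin).  An emptied cluster is re-seeded from the point currently
    farthest from its assigned centroid.
    """
    centers = X[init_idx].copy()
    k = len(centers)
    labels = np.full(len(X), -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        wcss = float(d2[np.arange(len(X)), new_labels].sum())
        history.append(wcss)
        assigned_d = d2[np.arange(len(X)), new_labels].copy()
        for c in range(k):
            if not np.any(new_labels == c):
                farthest = int(np.argmax(assigned_d))
                new_labels[farthest] = c
                assigned_d[farthest] = -np.inf
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    d2 = cdist(X, centers, metric="sqeuclidean")
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, wcss, history


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz dispersion ratio (B/(k-1)) / (W/(n-k))."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n clusters")
    overall = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in ks:
        sub = X[labels == c]
        center = sub.mean(axis=0)
        B += len(sub) * float(np.sum((center - overall) ** 2))
        W += float(np.sum((sub - center) ** 2))
    return (B / (k - 1)) / (W / (n - k))


@dataclass
class ClusterResult:
    """Best-of-restarts k-means result with the CH model-selection trace."""

    assignments: pd.Series  # labels in 1..k
    centroids: np.ndarray
    wcss: float
    selected_k: int
    ch_scores: dict[int, float] = field(default_factory=dict)
    wcss_by_k: dict[int, float] = field(default_factory=dict)
    n_restarts: int = 100

    def to_csv(self, path) -> None:
        self.assignments.rename("cluster").rename_axis("item").to_csv(path)


def kmeans_select(
    matrix: pd.DataFrame,
    k_range=range(2, 11),
    n_restarts: int = 100,
    seed: int = 0,
    k: int | None = None,
) -> ClusterResult:
    """K-means with multi-restart and Calinski-Harabasz k selection.

    For each candidate k, ``n_restarts`` runs of Lloyd's algorithm start
    from random distinct points (restart r of candidate k uses the child
    seed ``(seed, k, r)`` of the master seed) and the run minimizing the
    WCSS is kept.  The reported clustering is the best run at the k
    maximizing the CH criterion (or at the fixed ``k`` if given).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    n = len(X)
    ks = [k] if k is not None else [kk for kk in k_range]
    if any(kk >= n or kk < 1 for kk in ks):
        raise ValueError("k must satisfy 1 <= k < n_items")
    best_by_k: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    ch_scores: dict[int, float] = {}
    for kk in ks:
        best = None
        for r in range(n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, kk, r]))
            init_idx = rng.choice(n, size=kk, replace=False)
            labels, centers, wcss, _ = _lloyd(X, init_idx)
            if best is None or wcss < best[2]:
                best = (labels, centers, wcss)
        best_by_k[kk] = best
        if kk >= 2:
            ch_scores[kk] = calinski_harabasz(X, best[0])
    if k is not None:
        selected = k
    else:
        selected = max(ch_scores, key=ch_scores.get)
    labels, centers, wcss = best_by_k[selected]
    return ClusterResult(
        assignments=pd.Series(labels + 1, index=matrix.index),
        centroids=centers,
        wcss=wcss,
        selected_k=selected,
        ch_scores=ch_scores,
        wcss_by_k={kk: v[2] for kk, v in best_by_k.items()},
        n_restarts=n_restarts,
    )
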
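"""K-means grouping of z-scored profiles into prototypical responses.

Profiles are clustered on Euclidean distance over time points; the number of
clusters is chosen from the within-cluster sum-of-squares (WSS) curve, with
k = 6 as the pipeline default for this kind of stimulation time course.
Centroids are the mean z-scored profile of cluster members and can be
compared across transcript classes with a Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray       # gene index -> cluster id in 1..k
    centroids: np.ndarray    # k x T mean member profiles
    wss: float
    k: int
    seed: int


def kmeans_profiles(profiles: np.ndarray, k: int, seed: int = 0,
                    n_init: int = 25) -> ClusterResult:
    """Best-of-``n_init`` k-means with k-means++ seeding; deterministic per seed.

    ``profiles`` is an (n_genes, n_times) array of z-scored values; rows must
    be non-degenerate.  Labels are reported 1-based; centroids are recomputed
    as exact member means.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of profiles ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = km.labels_.astype(int)
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    wss = float(((X - centroids[labels]) ** 2).sum())
    return ClusterResult(labels=labels + 1, centroids=centroids, wss=wss,
                         k=k, seed=seed)


def wss_curve(profiles: np.ndarray, k_range, seed: int = 0,
              n_init: int = 25) -> list[tuple[int, float]]:
    """Total WSS for each k (fixed RNG stream per k)."""
    return [(int(k), kmeans_profiles(profiles, int(k), seed=seed, n_init=n_init).wss)
            for k in k_range]


def elbow_k(curve: list[tuple[int, float]]) -> int:
    """Automatic elbow: k with the largest second difference of the WSS curve.

    Requires at least three consecutive k values; the pipeline default
    remains k = 6 regardless, this helper only reports the curve's own bend.
    """
    ks = [k for k, _ in curve]
    ws = [w for _, w in curve]
    if len(ks) < 3:
        raise ValueError("need >= 3 k values for an elbow")
    second = [ws[i - 1] - 2 * ws[i] + ws[i + 1] for i in range(1, len(ws) - 1)]
    return ks[1 + int(np.argmax(second))]


def centroid_correlation(centroids_a: np.ndarray,
                         centroids_b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of centroid profiles.

    Constant centroids have undefined correlation and are reported as NaN.
    """
    A = np.asarray(centroids_a, dtype=float)
    B = np.asarray(centroids_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("centroid time grids differ")
    out = np.full((A.shape[0], B.shape[0]), np.nan)
    for i, a in enumerate(A):
        if np.ptp(a) == 0.0:
            continue
        for j, b in enumerate(B):
            if np.ptp(b) == 0.0:
                continue
            out[i, j] = float(np.corrcoef(a, b)[0, 1])
    return out
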
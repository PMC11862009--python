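"""Condensate detection in simulation frames.

Bound monomers (attraction > 0) are grouped by single-linkage agglomerative
clustering; the dendrogram is cut at the merge height whose flat clustering
maximizes the mean silhouette coefficient.  If no candidate cut achieves a
positive silhouette the frame is reported as a single cluster.  Cluster
centroids get normalized radial (R = |centroid| / a) and peripheral
(P = distance to shell surface / c) positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .polymer.shell import ShellSpec, ellipsoid_surface_distance


@dataclass
class ClusterResult:
    frame: int
    labels: np.ndarray  # one label per bound monomer, 1..k
    n_clusters: int
    silhouette: float
    centroids: np.ndarray  # (k, 3) sigma
    sizes: np.ndarray  # (k,) monomer counts
    radial_r: np.ndarray | None = None
    peripheral_p: np.ndarray | None = None
    min_size: int = 3

    @property
    def condensate_mask(self) -> np.ndarray:
        """Clusters large enough to count as condensates."""
        return self.sizes >= self.min_size

    @property
    def n_condensates(self) -> int:
        return int(self.condensate_mask.sum())


def cluster_condensates(
    positions: np.ndarray, min_size: int = 3, frame: int = 0
) -> ClusterResult:
    """Single-linkage clustering with silhouette-selected cut.

    Candidate cuts are the distinct merge heights of the dendrogram; every
    cut producing 2 <= k <= n-1 clusters is scored by the mean silhouette
    (Euclidean, same coordinates as the linkage) and the best is kept.
    Ties break toward fewer clusters.
    """
    pts = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return ClusterResult(frame, np.zeros(0, int), 0, np.nan,
                             np.zeros((0, 3)), np.zeros(0, int), min_size=min_size)
    if n == 1:
        return ClusterResult(frame, np.ones(1, int), 1, np.nan,
                             pts.copy(), np.ones(1, int), min_size=min_size)
    link = linkage(pts, method="single")
    heights = np.unique(link[:, 2])
    best_labels, best_sil, best_k = None, 0.0, None
    for h in heights:
        labels = fcluster(link, t=h, criterion="distance")
        k = labels.max()
        if not 2 <= k <= n - 1:
            continue
        sil = float(silhouette_score(pts, labels, metric="euclidean"))
        better = sil > best_sil + 1e-12
        tie = abs(sil - best_sil) <= 1e-12 and best_k is not None and k < best_k
        if best_labels is None and sil > 0 or better or tie:
            best_labels, best_sil, best_k = labels, sil, k
    if best_labels is None or best_sil <= 0:
        best_labels = np.ones(n, dtype=int)
        best_sil = np.nan
    k = int(best_labels.max())
    centroids = np.array([pts[best_labels == c].mean(axis=0) for c in range(1, k + 1)])
    sizes = np.array([(best_labels == c).sum() for c in range(1, k + 1)])
    return ClusterResult(
        frame=frame, labels=np.asarray(best_labels), n_clusters=k,
        silhouette=float(best_sil) if best_labels.max() > 1 else np.nan,
        centroids=centroids, sizes=sizes, min_size=min_size,
    )


def normalized_positions(result: ClusterResult, shell: ShellSpec) -> ClusterResult:
    """Attach normalized radial and peripheral centroid positions."""
    if len(result.centroids) == 0:
        result.radial_r = np.zeros(0)
        result.peripheral_p = np.zeros(0)
        return result
    cen = result.centroids
    result.radial_r = np.linalg.norm(cen, axis=1) / shell.a
    dist = np.array([ellipsoid_surface_distance(p, shell.a, shell.c) for p in cen])
    outside = shell.normalized_radius(cen) > 1.0
    if outside.any():
        dist = np.where(outside, -dist, dist)  # flag escape; confinement bug
    result.peripheral_p = dist / shell.c
    return result


def cluster_trajectory(
    frames: list[np.ndarray],
    bound_mask: np.ndarray,
    shell: ShellSpec | None = None,
    min_size: int = 3,
    all_monomers: bool = False,
) -> pd.DataFrame:
    """Cluster every frame and return a long-format condensate table with
    one row per condensate (frame, cluster, size, silhouette, R, P)."""
    mask = np.ones(len(bound_mask), bool) if all_monomers else np.asarray(bound_mask)
    rows = []
    for fi, pos in enumerate(frames):
        res = cluster_condensates(pos[mask], min_size=min_size, frame=fi)
        if shell is not None:
            res = normalized_positions(res, shell)
        for c in range(res.n_clusters):
            if res.sizes[c] < min_size:
                continue
            rows.append(
                {
                    "frame": fi,
                    "cluster": c + 1,
                    "size": int(res.sizes[c]),
                    "silhouette": res.silhouette,
                    "n_clusters": res.n_clusters,
                    "R": res.radial_r[c] if res.radial_r is not None else np.nan,
                    "P": res.peripheral_p[c] if res.peripheral_p is not None else np.nan,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["frame", "cluster", "size", "silhouette", "n_clusters", "R", "P"],
    )
    return df.astype(
        {"frame": "int64", "cluster": "int64", "size": "int64",
         "silhouette": "float64", "n_clusters": "int64",
         "R": "float64", "P": "float64"}
    )


def condensate_count_distribution(
    tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-condition condensate-count summaries over frames.

    ``tables`` maps condition labels (e.g. shape/level) to cluster tables
    from :func:`cluster_trajectory`.  Pairwise comparisons are left to
    :mod:`nucmech.stats_report`.
    """
    rows = []
    for label, df in tables.items():
        counts = (
            df.groupby("frame")["cluster"].count()
            if len(df)
            else pd.Series(dtype=float)
        )
        rows.append(
            {
                "condition": label,
                "n_frames": int(counts.shape[0]),
                "mean_count": float(counts.mean()) if len(counts) else np.nan,
                "median_count": float(counts.median()) if len(counts) else np.nan,
                "mean_size": float(df["size"].mean()) if len(df) else np.nan,
            }
        )
    return pd.DataFrame(rows)
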
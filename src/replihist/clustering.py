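"""Density-based segmentation of histone conglomerates and replication sites.

DBSCAN (3D Euclidean, self-inclusive MinPts counting) with the defaults used
throughout the analysis: eps = 75 nm, MinPts = 10, and a 100-detection minimum
for replication sites.  Cluster volumes come from 3D convex hulls; normalized
density is (n_detections / N_nucleus) / hull_volume.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from replihist import locio

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    eps_nm: float = 75.0
    min_pts: int = 10
    site_min_detections: int = 100

    def __post_init__(self):
        if self.eps_nm <= 0:
            raise ValueError("eps_nm must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class Conglomerate:
    """A DBSCAN cluster of localizations with its summary metrics."""

    label: int
    member_indices: np.ndarray
    coords: np.ndarray  # (n, 3) member coordinates, nm
    centroid: np.ndarray  # (3,) unweighted mean
    n_detections: int
    hull_volume_nm3: float
    degenerate_hull: bool
    normalized_density: float | None  # None for degenerate hulls


@dataclass
class ReplicationSite(Conglomerate):
    peripheral: bool | None = None


def dbscan_labels(coords: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN cluster labels for points given in scan order.

    A point is core iff >= ``min_pts`` points (itself included) lie within
    ``eps``.  Clusters are maximal density-connected sets; border points join
    the cluster of the first core neighbor reached in scan order; everything
    else is labelled ``NOISE`` (-1).  Cluster ids are assigned 0, 1, ... in
    order of the first core point encountered.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r=eps)
    core = np.array([len(nb) >= min_pts for nb in neighborhoods])

    cluster = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != NOISE:
            continue
        labels[seed] = cluster
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in sorted(neighborhoods[p]):
                if labels[q] == NOISE:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(q)
        cluster += 1
    return labels


def dbscan(table: pd.DataFrame, params: DbscanParams = DbscanParams()) -> np.ndarray:
    """Cluster a localization table; returns one label per input row.

    Scan order (hence border-point assignment and label numbering) is the
    canonical (frame, x, y, z) order, so the result is independent of the
    row permutation of ``table``.
    """
    locio.validate_localizations(table)
    if len(table) == 0:
        raise ValueError("cannot cluster an empty table")
    order = table.reset_index(drop=True).sort_values(
        ["frame", "x", "y", "z"], kind="mergesort"
    ).index.to_numpy()
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)[order]
    sorted_labels = dbscan_labels(coords, params.eps_nm, params.min_pts)
    labels = np.empty(len(table), dtype=np.int64)
    labels[order] = sorted_labels
    return labels


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """3D convex hull volume in nm^3 and a degeneracy flag.

    Degenerate inputs (fewer than 4 points, or coplanar/collinear sets) get
    volume 0.0 with ``degenerate=True``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(points) < 1:
        raise ValueError("need at least one point")
    if len(points) < 4:
        return 0.0, True
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def equivalent_sphere_diameter(volume_nm3: float) -> float:
    """Diameter (nm) of the sphere with the given volume."""
    if volume_nm3 < 0:
        raise ValueError("volume must be non-negative")
    return 2.0 * (3.0 * volume_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def conglomerate_metrics(
    labels: np.ndarray, table: pd.DataFrame, n_nucleus: int
) -> list[Conglomerate]:
    """Per-cluster centroid, hull volume and normalized density.

    normalized_density = (n_detections / n_nucleus) / hull_volume; clusters
    with degenerate (zero-volume) hulls carry ``normalized_density=None`` and
    are meant to be excluded from density distributions.
    """
    labels = np.asarray(labels)
    if n_nucleus <= 0:
        raise ValueError("n_nucleus must be positive")
    n_clustered = int((labels != NOISE).sum())
    if n_nucleus < n_clustered:
        raise ValueError(
            f"n_nucleus ({n_nucleus}) smaller than clustered detections ({n_clustered})"
        )
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    out = []
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        idx = np.nonzero(labels == lab)[0]
        pts = coords[idx]
        vol, degen = hull_volume(pts)
        density = None if degen else (len(idx) / n_nucleus) / vol
        out.append(
            Conglomerate(
                label=int(lab),
                member_indices=idx,
                coords=pts,
                centroid=pts.mean(axis=0),
                n_detections=len(idx),
                hull_volume_nm3=vol,
                degenerate_hull=degen,
                normalized_density=density,
            )
        )
    return out


def detect_replication_sites(
    edu_table: pd.DataFrame,
    params: DbscanParams = DbscanParams(),
    n_nucleus: int | None = None,
    strict_threshold: bool = False,
) -> list[ReplicationSite]:
    """DBSCAN clusters of the EdU channel passing the site size threshold.

    Clusters with fewer than ``params.site_min_detections`` detections are
    discarded (``strict_threshold`` switches >= to a strict >).
    """
    if len(edu_table) == 0:
        return []
    labels = dbscan(edu_table, params)
    if n_nucleus is None:
        n_nucleus = len(edu_table)
    sites = []
    for c in conglomerate_metrics(labels, edu_table, n_nucleus):
        keep = (
            c.n_detections > params.site_min_detections
            if strict_threshold
            else c.n_detections >= params.site_min_detections
        )
        if keep:
            sites.append(
                ReplicationSite(
                    label=c.label,
                    member_indices=c.member_indices,
                    coords=c.coords,
                    centroid=c.centroid,
                    n_detections=c.n_detections,
                    hull_volume_nm3=c.hull_volume_nm3,
                    degenerate_hull=c.degenerate_hull,
                    normalized_density=c.normalized_density,
                )
            )
    return sites


def in_hull(points: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    """Boolean mask: which ``points`` lie inside the convex hull of
    ``hull_points`` (boundary counts as inside).  Degenerate hulls contain
    nothing."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    try:
        tri = Delaunay(hull_points)
    except QhullError:
        return np.zeros(len(points), dtype=bool)
    return tri.find_simplex(points) >= 0


def select_near_sites(
    conglomerates: list[Conglomerate],
    sites: list[ReplicationSite],
    max_distance_nm: float = 200.0,
    mode: str = "centroid_distance",
) -> list[Conglomerate]:
    """Conglomerates associated with replication sites.

    ``centroid_distance``: keep a conglomerate iff its centroid lies strictly
    closer than ``max_distance_nm`` to any site centroid.
    ``hull_containment``: keep iff its centroid lies inside any site hull.
    """
    if mode not in ("centroid_distance", "hull_containment"):
        raise ValueError(f"unknown mode {mode!r}")
    if not sites:
        return []
    centroids = np.array([c.centroid for c in conglomerates]).reshape(-1, 3)
    if mode == "centroid_distance":
        site_centroids = np.array([s.centroid for s in sites])
        dists = np.linalg.norm(
            centroids[:, None, :] - site_centroids[None, :, :], axis=2
        )
        keep = (dists < max_distance_nm).any(axis=1)
    else:
        keep = np.zeros(len(conglomerates), dtype=bool)
        for s in sites:
            keep |= in_hull(centroids, s.coords)
    return [c for c, k in zip(conglomerates, keep) if k]


def clusters_to_frame(clusters: list[Conglomerate]) -> pd.DataFrame:
    """One-row-per-cluster summary CSV-ready table."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "label": c.label,
                "n_detections": c.n_detections,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
                "hull_volume_nm3": c.hull_volume_nm3,
                "degenerate_hull": c.degenerate_hull,
                "normalized_density": c.normalized_density,
                "peripheral": getattr(c, "peripheral", None),
            }
        )
    return pd.DataFrame(rows)
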
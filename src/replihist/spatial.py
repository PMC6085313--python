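"""Spatial statistics around replication sites.

Implements the quantitative readouts used downstream of clustering: per-site
parental recycling scores, 50 nm concentric-shell radial profiles, the
m-function (pair-distance enrichment against a uniform Monte-Carlo baseline),
2D Voronoi density maps, and KDE-based distribution comparisons with
peak-shift percentages and Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon

from replihist.clustering import Conglomerate, ReplicationSite, in_hull
from replihist.locio import NucleusMask


# ---------------------------------------------------------------------------
# recycling scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecyclingScore:
    site_label: int
    h: int          # parental detections inside the site hull
    e: int          # EdU detections of the site
    h_total: int    # parental detections in the whole nucleus
    score: float    # h / (e * h_total)


def recycling_scores(
    parental_table: pd.DataFrame, sites: list[ReplicationSite]
) -> list[RecyclingScore]:
    """Per-site parental signal normalized to EdU and to total parental signal.

    h is counted by convex-hull containment of parental detections in the
    site's hull; score = h / (e * H_total).
    """
    h_total = len(parental_table)
    if h_total == 0:
        raise ValueError("no parental detections in nucleus (H_total = 0)")
    pts = parental_table[["x", "y", "z"]].to_numpy(dtype=float)
    out = []
    for s in sites:
        h = int(in_hull(pts, s.coords).sum())
        out.append(
            RecyclingScore(
                site_label=s.label,
                h=h,
                e=s.n_detections,
                h_total=h_total,
                score=h / (s.n_detections * h_total),
            )
        )
    return out


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

def sphere_slab_volume(r: float, lo: float, hi: float) -> float:
    """Volume of a sphere of radius r (centered at 0) intersected with the
    horizontal slab lo <= z <= hi (offsets relative to the sphere center)."""
    a = max(-r, lo)
    b = min(r, hi)
    if b <= a:
        return 0.0
    def antideriv(t):
        return r * r * t - t**3 / 3.0
    return float(np.pi * (antideriv(b) - antideriv(a)))


def shell_volume(
    r_in: float, r_out: float, clip_mode: str = "none",
    z_offsets: tuple[float, float] | None = None,
) -> float:
    """Volume of the spherical shell [r_in, r_out), optionally clipped to a
    z slab given as offsets (lo, hi) from the shell center."""
    if clip_mode == "none":
        return 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
    if clip_mode == "slab":
        if z_offsets is None:
            raise ValueError("clip_mode='slab' requires z_offsets")
        lo, hi = z_offsets
        return sphere_slab_volume(r_out, lo, hi) - sphere_slab_volume(r_in, lo, hi)
    raise ValueError(f"unknown clip_mode {clip_mode!r}")


@dataclass
class RadialProfile:
    """Volume-normalized detection counts in concentric shells around a center."""

    edges: np.ndarray        # shell edges, nm (0, w, 2w, ...)
    counts: np.ndarray       # raw counts per shell
    volumes: np.ndarray      # shell volumes, nm^3
    center: np.ndarray
    clip_mode: str

    @property
    def densities(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.volumes > 0, self.counts / self.volumes, np.nan)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mean_distance(self) -> float:
        """Volume-density-weighted mean shell distance (profile centroid)."""
        d = self.densities
        ok = np.isfinite(d) & (d > 0)
        if not ok.any():
            return float("nan")
        return float(np.average(self.midpoints[ok], weights=d[ok]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_in": self.edges[:-1],
                "r_out": self.edges[1:],
                "count": self.counts,
                "volume_nm3": self.volumes,
                "density": self.densities,
            }
        )


def radial_profile(
    table: pd.DataFrame,
    center,
    max_radius_nm: float,
    shell_width_nm: float = 50.0,
    clip_mode: str = "none",
    z_bounds: tuple[float, float] | None = None,
    mask: NucleusMask | None = None,
) -> RadialProfile:
    """Assign detections to 50 nm concentric shells around ``center`` and
    normalize counts by shell volume.

    ``clip_mode='slab'`` uses the analytic intersection of each shell with
    the axial section ``z_bounds`` (or the mask's z interval).
    """
    if shell_width_nm <= 0:
        raise ValueError("shell_width_nm must be > 0")
    if clip_mode not in ("none", "slab"):
        raise ValueError(f"unknown clip_mode {clip_mode!r}")
    center = np.asarray(center, dtype=float)
    if mask is not None and not bool(
        mask.contains_xy(np.array([center[0]]), np.array([center[1]]))[0]
    ):
        warnings.warn("radial_profile: center lies outside the nucleus mask")
    if clip_mode == "slab":
        if z_bounds is None:
            if mask is None:
                raise ValueError("clip_mode='slab' requires z_bounds or mask")
            z_bounds = (mask.z_min, mask.z_max)
        z_offsets = (z_bounds[0] - center[2], z_bounds[1] - center[2])
    else:
        z_offsets = None

    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(coords - center, axis=1)
    n_shells = int(np.ceil(max_radius_nm / shell_width_nm))
    edges = shell_width_nm * np.arange(n_shells + 1)
    counts = np.histogram(d, bins=edges)[0]
    volumes = np.array(
        [
            shell_volume(edges[i], edges[i + 1], clip_mode, z_offsets)
            for i in range(n_shells)
        ]
    )
    return RadialProfile(edges=edges, counts=counts.astype(np.int64),
                         volumes=volumes, center=center, clip_mode=clip_mode)


def pool_radial_profiles(profiles: list[RadialProfile], per_site_average: bool = False) -> RadialProfile:
    """Pool profiles across sites: sum counts and volumes per shell, then
    normalize (default), or average per-site densities if requested."""
    if not profiles:
        raise ValueError("no profiles to pool")
    edges = profiles[0].edges
    for p in profiles:
        if not np.array_equal(p.edges, edges):
            raise ValueError("profiles have mismatched shell edges")
    counts = np.sum([p.counts for p in profiles], axis=0)
    if per_site_average:
        dens = np.nanmean([p.densities for p in profiles], axis=0)
        volumes = np.where(dens > 0, counts / dens, 0.0)
    else:
        volumes = np.sum([p.volumes for p in profiles], axis=0)
    return RadialProfile(edges=edges, counts=counts, volumes=volumes,
                         center=np.full(3, np.nan), clip_mode=profiles[0].clip_mode)


# ---------------------------------------------------------------------------
# m-function
# ---------------------------------------------------------------------------

@dataclass
class MFunctionCurve:
    radii: np.ndarray
    m: np.ndarray
    numerator: np.ndarray       # smoothed A-B pair-distance density
    baseline: np.ndarray        # mean over uniform-uniform replicates
    n_baseline: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_nm": self.radii, "m": self.m})


def _pair_distance_density(
    coords_a: np.ndarray, coords_b: np.ndarray, radii: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian-kernel-smoothed density of all A-B pair distances at ``radii``.

    Distances are histogrammed at bandwidth/4 resolution (pair counting with a
    KD-tree) and then kernel-smoothed, which is equivalent to a KDE on the
    25e6-size distance list at far lower cost.  An arbitrary common
    normalization is irrelevant: it cancels in the m ratio.
    """
    r_max = float(radii.max() + 5.0 * bandwidth)
    step = bandwidth / 4.0
    edges = np.arange(0.0, r_max + step, step)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    cum = tree_a.count_neighbors(tree_b, edges)
    hist = np.diff(cum).astype(float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    # kernel matrix (len(radii) x n_bins)
    k = np.exp(-0.5 * ((radii[:, None] - mids[None, :]) / bandwidth) ** 2)
    dens = k @ hist
    return dens / (len(coords_a) * len(coords_b))


def m_function(
    table_a,
    table_b,
    mask: NucleusMask,
    radii=None,
    bandwidth_nm: float = 25.0,
    n_baseline: int = 20,
    seed: int | None = None,
) -> MFunctionCurve:
    """Distance-resolved A-vs-B enrichment normalized to a random baseline.

    The numerator is the smoothed density of all A-B pair distances; the
    denominator is the mean of the same statistic over ``n_baseline`` pairs of
    uniform samples (matching sizes) drawn inside ``mask``.  m = 1 indicates
    independence, > 1 attraction, < 1 repulsion.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    coords_a = _as_coords(table_a)
    coords_b = _as_coords(table_b)
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ValueError("both point sets must be non-empty")
    if radii is None:
        radii = np.arange(25.0, 1000.1, 25.0)
    radii = np.asarray(radii, dtype=float)

    num = _pair_distance_density(coords_a, coords_b, radii, bandwidth_nm)
    rng = np.random.default_rng(seed)
    base = np.zeros_like(num)
    for _ in range(n_baseline):
        ua = mask.sample_points(len(coords_a), rng)
        ub = mask.sample_points(len(coords_b), rng)
        base += _pair_distance_density(ua, ub, radii, bandwidth_nm)
    base /= n_baseline
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(base > 0, num / base, np.nan)
    return MFunctionCurve(radii=radii, m=m, numerator=num, baseline=base,
                          n_baseline=n_baseline, seed=seed)


def _as_coords(table_or_coords) -> np.ndarray:
    if isinstance(table_or_coords, pd.DataFrame):
        return table_or_coords[["x", "y", "z"]].to_numpy(dtype=float)
    return np.asarray(table_or_coords, dtype=float)


# ---------------------------------------------------------------------------
# Voronoi density
# ---------------------------------------------------------------------------

@dataclass
class VoronoiDensityMap:
    areas_nm2: np.ndarray        # one clipped polygon area per detection
    polygons: list | None
    mask_area_nm2: float

    def small_area_fraction(self, cutoff_nm2: float) -> float:
        return float(np.mean(self.areas_nm2 < cutoff_nm2))

    def summary(self) -> dict:
        return {
            "n": int(len(self.areas_nm2)),
            "median_nm2": float(np.median(self.areas_nm2)),
            "mean_nm2": float(np.mean(self.areas_nm2)),
            "total_nm2": float(np.sum(self.areas_nm2)),
        }


def _finite_voronoi_regions(vor: Voronoi, radius: float):
    """Close the unbounded Voronoi regions by extending their open ridges to
    ``radius`` (standard finite-polygon reconstruction for 2D diagrams)."""
    new_regions = []
    new_vertices = vor.vertices.tolist()
    center = vor.points.mean(axis=0)
    all_ridges: dict[int, list] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        all_ridges.setdefault(p1, []).append((p2, v1, v2))
        all_ridges.setdefault(p2, []).append((p1, v1, v2))
    for p1, region_idx in enumerate(vor.point_region):
        vertices = vor.regions[region_idx]
        if all(v >= 0 for v in vertices):
            new_regions.append(vertices)
            continue
        region = [v for v in vertices if v >= 0]
        for p2, v1, v2 in all_ridges.get(p1, []):
            if v2 < 0:
                v1, v2 = v2, v1
            if v1 >= 0:
                continue
            tangent = vor.points[p2] - vor.points[p1]
            tangent = tangent / np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = vor.points[[p1, p2]].mean(axis=0)
            direction = np.sign(np.dot(midpoint - center, normal)) * normal
            far_point = vor.vertices[v2] + direction * radius
            region.append(len(new_vertices))
            new_vertices.append(far_point.tolist())
        vs = np.asarray([new_vertices[v] for v in region])
        c = vs.mean(axis=0)
        angles = np.arctan2(vs[:, 1] - c[1], vs[:, 0] - c[0])
        region = [region[i] for i in np.argsort(angles)]
        new_regions.append(region)
    return new_regions, np.asarray(new_vertices)


def voronoi_density(
    table: pd.DataFrame,
    mask: NucleusMask,
    keep_polygons: bool = False,
) -> VoronoiDensityMap:
    """2D Voronoi tessellation of xy detections clipped to the nucleus mask.

    Each detection gets the area of its polygon; exterior-touching cells are
    clipped to the mask boundary.  Exact duplicate points are jittered by
    < 0.1 nm (with a warning) so the tessellation is well defined.
    """
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if len(xy) < 4:
        raise ValueError("need >= 4 points for a Voronoi tessellation")
    _, inverse, counts = np.unique(
        xy, axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        warnings.warn("duplicate xy points jittered by < 0.1 nm for tessellation")
        rng = np.random.default_rng(0)
        dup = counts[inverse] > 1
        xy = xy.copy()
        xy[dup] += rng.uniform(-0.05, 0.05, (int(dup.sum()), 2))
    vor = Voronoi(xy)
    minx, miny, maxx, maxy = mask.polygon.bounds
    radius = 10.0 * max(maxx - minx, maxy - miny)
    regions, vertices = _finite_voronoi_regions(vor, radius)
    areas = np.empty(len(xy))
    polys = [] if keep_polygons else None
    for i, region in enumerate(regions):
        cell = Polygon(vertices[region]).intersection(mask.polygon)
        areas[i] = cell.area
        if keep_polygons:
            polys.append(cell)
    return VoronoiDensityMap(areas_nm2=areas, polygons=polys,
                             mask_area_nm2=mask.area_nm2)


# ---------------------------------------------------------------------------
# distribution comparisons
# ---------------------------------------------------------------------------

def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class DistributionComparison:
    grid: np.ndarray
    kde_a: np.ndarray | None
    kde_b: np.ndarray | None
    peak_a: float
    peak_b: float
    peak_shift_percent: float
    u_statistic: float
    p_value: float
    stars: str
    point_mass_a: bool
    point_mass_b: bool


def _kde_peak(sample: np.ndarray, grid: np.ndarray, bandwidth_rule: str):
    if np.ptp(sample) == 0:
        return None, float(sample[0]), True
    kde = stats.gaussian_kde(sample, bw_method=bandwidth_rule)
    dens = kde(grid)
    return dens, float(grid[int(np.argmax(dens))]), False


def compare_distributions(
    samples_a,
    samples_b,
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
) -> DistributionComparison:
    """KDE peaks, peak-shift percentage and a two-sided Mann-Whitney U test.

    peak_shift_percent = 100 * (peak_B - peak_A) / peak_A, the reporting
    convention used for all density/volume/recycling comparisons.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample must have >= 5 values")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    grid = np.linspace(lo, hi, grid_size)
    kde_a, peak_a, pm_a = _kde_peak(a, grid, bandwidth_rule)
    kde_b, peak_b, pm_b = _kde_peak(b, grid, bandwidth_rule)
    shift = 100.0 * (peak_b - peak_a) / peak_a if peak_a != 0 else float("nan")

    exact_ok = (
        len(np.unique(pooled)) == len(pooled) and max(len(a), len(b)) <= 25
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact_ok else "auto"
    )
    return DistributionComparison(
        grid=grid, kde_a=kde_a, kde_b=kde_b,
        peak_a=peak_a, peak_b=peak_b, peak_shift_percent=float(shift),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        stars=star_code(float(res.pvalue)),
        point_mass_a=pm_a, point_mass_b=pm_b,
    )


# ---------------------------------------------------------------------------
# periphery classification
# ---------------------------------------------------------------------------

def classify_periphery(
    sites: list[ReplicationSite],
    mask: NucleusMask,
    peripheral_band_nm: float = 500.0,
) -> list[ReplicationSite]:
    """Flag sites whose centroid lies within ``peripheral_band_nm`` of the
    2D mask boundary (sites outside the mask are peripheral too)."""
    edge = mask.polygon.exterior
    for s in sites:
        p = Point(s.centroid[0], s.centroid[1])
        s.peripheral = bool(edge.distance(p) < peripheral_band_nm)
    return sites
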
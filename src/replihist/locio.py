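"""Localization-table I/O and pre-analysis corrections.

Localization tables are plain :class:`pandas.DataFrame` objects with columns
``x``, ``y``, ``z`` (nm), ``frame`` (int >= 0) and ``channel`` (str/int), plus
an optional ``intensity`` column.  All operations are deterministic and
order-stable: results do not depend on the input row permutation (ties broken
by ``(frame, x, y, z)`` lexicographic order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from shapely import contains_xy as _shapely_contains_xy
from shapely.geometry import Point, Polygon

REQUIRED_COLUMNS = ("x", "y", "z", "frame", "channel")

#: header name -> canonical column, per supported dialect
DIALECTS = {
    "generic": {"x": "x", "y": "y", "z": "z", "frame": "frame", "channel": "channel"},
    "thunderstorm": {
        "x [nm]": "x",
        "y [nm]": "y",
        "z [nm]": "z",
        "frame": "frame",
        "channel": "channel",
    },
}


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


class DriftError(ValueError):
    """Raised when drift estimation or application is impossible."""


class SegmentationError(ValueError):
    """Raised when a nucleus mask cannot be built."""


def validate_localizations(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"localization table missing column(s): {missing}")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise FormatError("non-finite coordinates in localization table")
    if (table["frame"].to_numpy() < 0).any():
        raise FormatError("negative frame indices in localization table")
    return table


def canonical_order(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: sort by (frame, x, y, z), reset index."""
    out = table.sort_values(
        ["frame", "x", "y", "z"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def read_localizations(
    path,
    dialect: str = "generic",
    pixel_size_nm: float | None = None,
) -> pd.DataFrame:
    """Read a localization CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        ``"generic"`` (columns x/y/z/frame/channel) or ``"thunderstorm"``
        (``x [nm]``-style headers).
    pixel_size_nm
        If given, x and y are interpreted as pixel units and converted to nm
        at read time (z is assumed to already be in nm).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    raw = pd.read_csv(path)
    rename = {src: dst for src, dst in mapping.items() if src in raw.columns}
    table = raw.rename(columns=rename)
    if "channel" not in table.columns:
        table["channel"] = 0
    for col in ("x", "y", "z", "frame"):
        if col not in table.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} for dialect {dialect!r}"
            )
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any() or numeric.isna().any():
            # +2: header line and 1-based numbering
            line = int(numeric.index[numeric.isna()][0]) + 2
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        table[col] = numeric
    if pixel_size_nm is not None:
        table["x"] = table["x"] * float(pixel_size_nm)
        table["y"] = table["y"] * float(pixel_size_nm)
    table["frame"] = table["frame"].astype(np.int64)
    keep = [c for c in ("x", "y", "z", "frame", "channel", "intensity") if c in table.columns]
    return validate_localizations(table[keep])


def write_localizations(table: pd.DataFrame, path) -> None:
    validate_localizations(table)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftModel:
    """Per-frame offset (dx, dy, dz) in nm; offset at the reference frame is 0."""

    frames: np.ndarray
    offsets: np.ndarray  # shape (n_frames, 3)
    reference_frame: int

    def offset_at(self, frames) -> np.ndarray:
        frames = np.asarray(frames)
        idx = {f: i for i, f in enumerate(self.frames)}
        missing = sorted(set(frames.tolist()) - idx.keys())
        if missing:
            raise DriftError(f"drift model does not cover frames: {missing[:10]}")
        return self.offsets[[idx[f] for f in frames.tolist()]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "dx": self.offsets[:, 0],
             "dy": self.offsets[:, 1], "dz": self.offsets[:, 2]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_frame: int | None = None) -> "DriftModel":
        frames = df["frame"].to_numpy(dtype=np.int64)
        offsets = df[["dx", "dy", "dz"]].to_numpy(dtype=float)
        ref = int(frames[0]) if reference_frame is None else int(reference_frame)
        return cls(frames=frames, offsets=offsets, reference_frame=ref)


def estimate_drift(
    beads: pd.DataFrame,
    smoothing_window: int = 100,
    reference_frame: int | None = None,
) -> DriftModel:
    """Estimate per-frame drift from fiducial bead tracks.

    ``beads`` must have columns bead, frame, x, y, z.  The per-frame offset is
    the mean over beads of (position - position at the reference frame),
    smoothed with a centered moving average of width ``smoothing_window``, and
    re-anchored so the reference-frame offset is exactly zero.
    """
    for col in ("bead", "frame", "x", "y", "z"):
        if col not in beads.columns:
            raise FormatError(f"bead track missing column {col!r}")
    if beads["frame"].nunique() < 2:
        raise DriftError("need at least 2 frames to estimate drift")
    frame_sets = beads.groupby("bead")["frame"].agg(set)
    common = set.intersection(*frame_sets.tolist())
    if not common:
        raise DriftError("no frames in common across beads")
    ref = min(common) if reference_frame is None else reference_frame
    if ref not in common:
        raise DriftError(f"reference frame {ref} not observed for every bead")

    frames = np.sort(beads["frame"].unique()).astype(np.int64)
    cols = []
    for axis in ("x", "y", "z"):
        wide = beads.pivot_table(index="frame", columns="bead", values=axis)
        rel = wide - wide.loc[ref]
        mean = rel.mean(axis=1).loc[frames].to_numpy()
        smooth = _centered_moving_average(mean, smoothing_window)
        ref_pos = int(np.searchsorted(frames, ref))
        cols.append(smooth - smooth[ref_pos])  # enforce offset(ref) = 0
    arr = np.column_stack(cols)
    return DriftModel(frames=frames, offsets=arr, reference_frame=int(ref))


def _centered_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically near the
    ends, so the filter is exact on linear trends everywhere (no edge bias)."""
    n = len(values)
    half = max(int(window) // 2, 0)
    cum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), half)
    return (cum[idx + k + 1] - cum[idx - k]) / (2 * k + 1)


def apply_drift(table: pd.DataFrame, model: DriftModel, inverse: bool = False) -> pd.DataFrame:
    """Translate every record by -offset(frame) (or +offset if ``inverse``)."""
    validate_localizations(table)
    off = model.offset_at(table["frame"].to_numpy())
    sign = 1.0 if inverse else -1.0
    out = table.copy()
    out[["x", "y", "z"]] = out[["x", "y", "z"]].to_numpy(dtype=float) + sign * off
    return out


# ---------------------------------------------------------------------------
# channel registration
# ---------------------------------------------------------------------------

_MIN_BEADS = {"translation": 1, "rigid": 3, "affine": 4}


@dataclass(frozen=True)
class ChannelTransform:
    """Linear 3D map ``A ~= matrix @ B + translation`` fit from matched beads."""

    matrix: np.ndarray        # (3, 3)
    translation: np.ndarray   # (3,)
    kind: str
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "ChannelTransform":
        inv = np.linalg.inv(self.matrix)
        return ChannelTransform(
            matrix=inv, translation=-inv @ self.translation,
            kind=self.kind, residual_rms=self.residual_rms,
        )

    def apply_table(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[["x", "y", "z"]] = self.apply(out[["x", "y", "z"]].to_numpy(dtype=float))
        return out


def _matched_bead_positions(beads_a: pd.DataFrame, beads_b: pd.DataFrame):
    pa = beads_a.groupby("bead")[["x", "y", "z"]].mean()
    pb = beads_b.groupby("bead")[["x", "y", "z"]].mean()
    ids = sorted(set(pa.index) & set(pb.index))
    return pa.loc[ids].to_numpy(), pb.loc[ids].to_numpy()


def register_channels(
    beads_a: pd.DataFrame, beads_b: pd.DataFrame, model_kind: str = "rigid"
) -> ChannelTransform:
    """Least-squares transform mapping channel-B bead positions onto channel A.

    ``model_kind`` is one of translation / rigid / affine (rigid = rotation +
    translation via the Kabsch algorithm).
    """
    if model_kind not in _MIN_BEADS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    a, b = _matched_bead_positions(beads_a, beads_b)
    if len(a) < _MIN_BEADS[model_kind]:
        raise ValueError(
            f"model_kind {model_kind!r} needs >= {_MIN_BEADS[model_kind]} matched beads, "
            f"got {len(a)}"
        )
    if model_kind == "translation":
        matrix = np.eye(3)
        translation = (a - b).mean(axis=0)
    elif model_kind == "rigid":
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        h = (b - cb).T @ (a - ca)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        matrix = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        translation = ca - matrix @ cb
    else:  # affine
        design = np.hstack([b, np.ones((len(b), 1))])
        coef, *_ = np.linalg.lstsq(design, a, rcond=None)
        matrix = coef[:3].T
        translation = coef[3]
    residual = a - (b @ matrix.T + translation)
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1)))) if len(a) else 0.0
    return ChannelTransform(matrix=matrix, translation=translation,
                            kind=model_kind, residual_rms=rms)


# ---------------------------------------------------------------------------
# consecutive-frame merging
# ---------------------------------------------------------------------------

def _greedy_frame_links(pos_f, pos_g, idx_f, idx_g, radius):
    """Greedy nearest-first matching between records of two consecutive frames.

    Ties broken by (distance, canonical index of f-record, canonical index of
    g-record).  Each record participates in at most one link.
    """
    if len(idx_f) == 0 or len(idx_g) == 0:
        return []
    tree = cKDTree(pos_g)
    pairs = tree.query_ball_point(pos_f, r=radius)
    cands = []
    for i, neigh in enumerate(pairs):
        for j in neigh:
            d = float(np.linalg.norm(pos_f[i] - pos_g[j]))
            cands.append((d, idx_f[i], idx_g[j], i, j))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_f, used_g, links = set(), set(), []
    for d, ki, kj, i, j in cands:
        if i in used_f or j in used_g:
            continue
        used_f.add(i)
        used_g.add(j)
        links.append((ki, kj))
    return links


def merge_consecutive(
    table: pd.DataFrame,
    radius_nm: float = 50.0,
    weight_by_intensity: bool = False,
) -> pd.DataFrame:
    """Collapse blink chains: localizations in consecutive frames within
    ``radius_nm`` are considered one molecule.

    Linking is greedy nearest-first per (frame, frame+1) pair and per channel;
    chains collapse transitively to a single record at the unweighted mean of
    the original member positions (intensity-weighted if requested), with
    frame = first frame of the chain.  The procedure is iterated to a fixed
    point so the operation is idempotent.
    """
    if radius_nm < 0:
        raise ValueError("radius_nm must be non-negative")
    validate_localizations(table)
    table = canonical_order(table)
    has_int = "intensity" in table.columns

    pieces = []
    for channel, sub in table.groupby("channel", sort=True):
        members = [[i] for i in sub.index]  # original canonical row indices
        frames = sub["frame"].to_numpy().tolist()
        xyz = [sub.loc[i, ["x", "y", "z"]].to_numpy(dtype=float) for i in sub.index]

        while True:
            order = sorted(range(len(members)), key=lambda k: (frames[k], *xyz[k]))
            by_frame: dict[int, list[int]] = {}
            for k in order:
                by_frame.setdefault(frames[k], []).append(k)
            parent = list(range(len(members)))

            def find(k):
                while parent[k] != k:
                    parent[k] = parent[parent[k]]
                    k = parent[k]
                return k

            n_links = 0
            for f in sorted(by_frame):
                if f + 1 not in by_frame:
                    continue
                ks_f, ks_g = by_frame[f], by_frame[f + 1]
                links = _greedy_frame_links(
                    np.array([xyz[k] for k in ks_f]),
                    np.array([xyz[k] for k in ks_g]),
                    ks_f, ks_g, radius_nm,
                )
                for ki, kj in links:
                    ri, rj = find(ki), find(kj)
                    if ri != rj:
                        parent[rj] = ri
                        n_links += 1
            if n_links == 0:
                break
            groups: dict[int, list[int]] = {}
            for k in range(len(members)):
                groups.setdefault(find(k), []).append(k)
            new_members, new_frames, new_xyz = [], [], []
            for ks in groups.values():
                mem = sorted(m for k in ks for m in members[k])
                orig = table.loc[mem]
                if weight_by_intensity and has_int:
                    w = orig["intensity"].to_numpy(dtype=float)
                    pos = (orig[["x", "y", "z"]].to_numpy(dtype=float) * w[:, None]).sum(0) / w.sum()
                else:
                    pos = orig[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
                new_members.append(mem)
                new_frames.append(int(orig["frame"].min()))
                new_xyz.append(pos)
            members, frames, xyz = new_members, new_frames, new_xyz

        piece = pd.DataFrame(
            {
                "x": [p[0] for p in xyz],
                "y": [p[1] for p in xyz],
                "z": [p[2] for p in xyz],
                "frame": frames,
                "channel": channel,
            }
        )
        if has_int:
            piece["intensity"] = [table.loc[m, "intensity"].sum() for m in members]
        pieces.append(piece)

    out = pd.concat(pieces, ignore_index=True) if pieces else table.iloc[:0].copy()
    return canonical_order(out)


def clip_z_section(table: pd.DataFrame, z_min: float, z_max: float) -> pd.DataFrame:
    """Keep records with z in the half-open interval [z_min, z_max)."""
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    validate_localizations(table)
    mask = (table["z"] >= z_min) & (table["z"] < z_max)
    return table.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# nucleus mask
# ---------------------------------------------------------------------------

@dataclass
class NucleusMask:
    """2D boundary polygon (nm) plus a z interval; the analysis region."""

    polygon: Polygon
    z_min: float
    z_max: float
    _prepared: object = field(default=None, repr=False, compare=False)

    @property
    def area_nm2(self) -> float:
        return float(self.polygon.area)

    @property
    def volume_nm3(self) -> float:
        return self.area_nm2 * (self.z_max - self.z_min)

    def contains_xy(self, x, y) -> np.ndarray:
        # boundary points count as inside (covers hull vertices)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = _shapely_contains_xy(self.polygon, x, y)
        if not inside.all():
            edge = self.polygon.boundary
            for i in np.nonzero(~inside)[0]:
                if edge.distance(Point(x.flat[i], y.flat[i])) < 1e-9:
                    inside.flat[i] = True
        return inside

    def contains(self, table: pd.DataFrame) -> np.ndarray:
        inz = (table["z"].to_numpy() >= self.z_min) & (table["z"].to_numpy() <= self.z_max)
        return self.contains_xy(table["x"].to_numpy(), table["y"].to_numpy()) & inz

    def boundary_distance_xy(self, x, y) -> np.ndarray:
        edge = self.polygon.exterior
        return np.array(
            [edge.distance(Point(px, py)) for px, py in zip(np.atleast_1d(x), np.atleast_1d(y))]
        )

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform 3D points inside polygon x z-interval (rejection sampling)."""
        minx, miny, maxx, maxy = self.polygon.bounds
        out = np.empty((n, 3))
        got = 0
        while got < n:
            m = max(2 * (n - got), 128)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            ok = _shapely_contains_xy(self.polygon, xs, ys)
            take = min(int(ok.sum()), n - got)
            sel = np.nonzero(ok)[0][:take]
            out[got : got + take, 0] = xs[sel]
            out[got : got + take, 1] = ys[sel]
            got += take
        out[:, 2] = rng.uniform(self.z_min, self.z_max, n)
        return out


def segment_nucleus(table: pd.DataFrame) -> NucleusMask:
    """Nucleus mask = 2D convex hull of all detections, z interval = z range."""
    validate_localizations(table)
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if len(xy) < 3:
        raise SegmentationError("need >= 3 points to segment a nucleus")
    try:
        hull = ConvexHull(xy)
    except Exception as exc:  # qhull degenerate input
        raise SegmentationError(f"degenerate (collinear?) xy points: {exc}") from exc
    poly = Polygon(xy[hull.vertices])
    z = table["z"].to_numpy(dtype=float)
    return NucleusMask(polygon=poly, z_min=float(z.min()), z_max=float(z.max()))


def ellipse_mask(
    semi_axis_x: float, semi_axis_y: float, z_half: float, n_vertices: int = 256
) -> NucleusMask:
    """Elliptical nucleus mask centered at the origin (z slab of +-z_half)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    poly = Polygon(np.column_stack([semi_axis_x * np.cos(theta), semi_axis_y * np.sin(theta)]))
    return NucleusMask(polygon=poly, z_min=-z_half, z_max=z_half)
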
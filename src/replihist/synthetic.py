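"""Synthetic inputs with planted ground truth.

Every input the real pipeline consumes from microscopes or sequencers can be
generated here: clustered two-channel 3D localization scenes (Thomas process
inside an elliptical nucleus cut by an axial section), fiducial bead tracks
with shared drift, genomic coverage tracks with planted replication-timing /
transcription / enrichment structure, and per-nucleus pulse-chase intensity
series.  All generators are deterministic given a seed, and emit the ground
truth needed for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from replihist.locio import NucleusMask, ellipse_mask

HISTONE_CHANNEL = "A"
EDU_CHANNEL = "B"


# ---------------------------------------------------------------------------
# localization scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a two-channel clustered localization scene.

    The nucleus is an xy ellipse crossed with a z slab (default 600 nm total
    thickness, i.e. the axial section actually imaged).  Conglomerates are
    Thomas-process clusters: Gaussian offspring of dispersion
    ``conglomerate_radius_nm`` around uniformly placed parents.
    ``channel_coupling`` controls how channel-A positions distribute around
    channel-B parents: 1 = independent, > 1 attraction, < 1 repulsion.
    """

    nucleus_semi_axes: tuple[float, float, float] = (8000.0, 5000.0, 300.0)
    n_conglomerates: int = 30
    conglomerate_radius_nm: float = 50.0
    detections_per_conglomerate: float = 200.0
    background_fraction: float = 0.05
    channel_coupling: float = 1.0
    coupling_range_nm: float = 150.0
    min_parent_separation_nm: float = 0.0
    drift_amplitude_nm: float = 0.0
    n_frames: int = 1000
    blink_repeat_prob: float = 0.0
    blink_jitter_nm: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if any(a <= 0 for a in self.nucleus_semi_axes):
            raise ValueError("nucleus semi-axes must be positive")
        if self.n_conglomerates < 0:
            raise ValueError("n_conglomerates must be >= 0")
        if self.conglomerate_radius_nm <= 0:
            raise ValueError("conglomerate_radius_nm must be > 0")
        if self.detections_per_conglomerate <= 0:
            raise ValueError("detections_per_conglomerate must be > 0")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.channel_coupling < 0:
            raise ValueError("channel_coupling must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.blink_repeat_prob < 1.0:
            raise ValueError("blink_repeat_prob must be in [0, 1)")
        if self.drift_amplitude_nm < 0:
            raise ValueError("drift_amplitude_nm must be >= 0")

    def mask(self) -> NucleusMask:
        ax, ay, az = self.nucleus_semi_axes
        return ellipse_mask(ax, ay, az)


@dataclass
class SceneTruth:
    """Ground truth for a generated scene, row-aligned with the table."""

    spec: SceneSpec
    parents: dict  # channel -> (k, 3) parent centers
    drift: np.ndarray  # (n_frames, 3)
    records: pd.DataFrame  # channel, cluster, molecule, true_x/y/z per row

    @property
    def n_clusters(self) -> dict:
        return {ch: len(p) for ch, p in self.parents.items()}

    def to_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "parents": {ch: np.asarray(p).tolist() for ch, p in self.parents.items()},
            "drift": self.drift.tolist(),
            "records": self.records.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SceneTruth":
        with open(path) as fh:
            payload = json.load(fh)
        spec = SceneSpec(**{
            **payload["spec"],
            "nucleus_semi_axes": tuple(payload["spec"]["nucleus_semi_axes"]),
        })
        return cls(
            spec=spec,
            parents={ch: np.asarray(p) for ch, p in payload["parents"].items()},
            drift=np.asarray(payload["drift"]),
            records=pd.DataFrame(payload["records"]),
        )


def _inside(mask: NucleusMask, pts: np.ndarray) -> np.ndarray:
    inz = (pts[:, 2] >= mask.z_min) & (pts[:, 2] <= mask.z_max)
    from shapely import contains_xy

    return contains_xy(mask.polygon, pts[:, 0], pts[:, 1]) & inz


def _truncated_gaussian(
    mask: NucleusMask, center: np.ndarray, sigma: float, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian offspring around ``center`` resampled until inside the mask."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(2 * (n - got), 32)
        cand = center + rng.normal(0.0, sigma, (m, 3))
        ok = _inside(mask, cand)
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = cand[ok][:take]
        got += take
    return out


def _hardcore_parents(
    mask: NucleusMask, n: int, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform parents with a hard-core minimum separation (dart throwing)."""
    if min_sep <= 0:
        return mask.sample_points(n, rng)
    out = np.empty((n, 3))
    got = 0
    attempts = 0
    while got < n:
        cand = mask.sample_points(1, rng)[0]
        if got == 0 or np.linalg.norm(out[:got] - cand, axis=1).min() >= min_sep:
            out[got] = cand
            got += 1
        attempts += 1
        if attempts > 10_000 * n:
            raise ValueError("cannot place parents at the requested separation")
    return out


def _biased_uniform(
    mask: NucleusMask, n: int, rng: np.random.Generator,
    attract_centers: np.ndarray | None, coupling: float, coupling_range: float,
) -> np.ndarray:
    """Uniform points reweighted by ``coupling`` within ``coupling_range`` of
    the attractor centers (coupling = 1 or no centers -> plain uniform)."""
    if attract_centers is None or len(attract_centers) == 0 or coupling == 1.0:
        return mask.sample_points(n, rng)
    tree = cKDTree(attract_centers)
    w_max = max(coupling, 1.0)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cand = mask.sample_points(m, rng)
        near = tree.query(cand, k=1)[0] < coupling_range
        w = np.where(near, coupling, 1.0)
        keep = rng.random(m) < w / w_max
        take = min(int(keep.sum()), n - got)
        out[got : got + take] = cand[keep][:take]
        got += take
    return out


def _drift_series(n_frames: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth shared drift: a random walk rescaled so the largest per-axis
    excursion equals ``amplitude``; zero at frame 0."""
    steps = rng.normal(0.0, 1.0, (n_frames, 3))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    if amplitude == 0.0:
        return np.zeros((n_frames, 3))
    peak = np.abs(walk).max(axis=0)
    peak[peak == 0] = 1.0
    return walk * (amplitude / peak)


def generate_scene(spec: SceneSpec) -> tuple[pd.DataFrame, SceneTruth]:
    """Generate a two-channel localization table plus its ground truth.

    Channel B carries the conglomerates that play the replication sites;
    channel A plays the histone signal, with its cluster parents (and
    background) attracted to or repelled from B parents according to
    ``channel_coupling``.  Each molecule is observed in one frame and may
    blink on in following frames (geometric chain, jittered re-detections).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = spec.mask()

    parents: dict[str, np.ndarray] = {}
    molecules = []  # (channel, cluster, position)
    # channel B first: its parents act as attractors for channel A
    for channel in (EDU_CHANNEL, HISTONE_CHANNEL):
        if spec.n_conglomerates > 0:
            if channel == HISTONE_CHANNEL and spec.channel_coupling != 1.0:
                centers = _biased_uniform(
                    mask, spec.n_conglomerates, rng, parents.get(EDU_CHANNEL),
                    spec.channel_coupling, spec.coupling_range_nm,
                )
            else:
                centers = _hardcore_parents(
                    mask, spec.n_conglomerates, spec.min_parent_separation_nm, rng
                )
        else:
            centers = np.empty((0, 3))
        parents[channel] = centers
        n_clustered = 0
        for ci, center in enumerate(centers):
            k = int(rng.poisson(spec.detections_per_conglomerate))
            if k == 0:
                continue
            pts = _truncated_gaussian(mask, center, spec.conglomerate_radius_nm, k, rng)
            for p in pts:
                molecules.append((channel, ci, p))
            n_clustered += k
        if spec.background_fraction >= 1.0:
            n_bg = int(round(spec.detections_per_conglomerate))
        elif spec.background_fraction > 0:
            n_bg = int(round(
                n_clustered * spec.background_fraction / (1.0 - spec.background_fraction)
            ))
        else:
            n_bg = 0
        if n_bg:
            if channel == HISTONE_CHANNEL:
                bg = _biased_uniform(
                    mask, n_bg, rng, parents.get(EDU_CHANNEL),
                    spec.channel_coupling, spec.coupling_range_nm,
                )
            else:
                bg = mask.sample_points(n_bg, rng)
            for p in bg:
                molecules.append((channel, -1, p))

    drift = _drift_series(spec.n_frames, spec.drift_amplitude_nm, rng)

    rows = []
    for mol_id, (channel, cluster, pos) in enumerate(molecules):
        frame = int(rng.integers(0, spec.n_frames))
        obs = pos
        while True:
            rows.append((channel, cluster, mol_id, pos, obs + drift[frame], frame))
            if frame + 1 >= spec.n_frames or rng.random() >= spec.blink_repeat_prob:
                break
            frame += 1
            obs = _truncated_gaussian(mask, pos, spec.blink_jitter_nm, 1, rng)[0]

    combined = pd.DataFrame(
        {
            "x": [r[4][0] for r in rows],
            "y": [r[4][1] for r in rows],
            "z": [r[4][2] for r in rows],
            "frame": [r[5] for r in rows],
            "channel": [r[0] for r in rows],
            "cluster": [r[1] for r in rows],
            "molecule": [r[2] for r in rows],
            "true_x": [r[3][0] for r in rows],
            "true_y": [r[3][1] for r in rows],
            "true_z": [r[3][2] for r in rows],
        }
    )
    combined = combined.sort_values(
        ["frame", "x", "y", "z"], kind="mergesort"
    ).reset_index(drop=True)
    table = combined[["x", "y", "z", "frame", "channel"]].copy()
    truth_records = combined[
        ["channel", "cluster", "molecule", "true_x", "true_y", "true_z"]
    ].copy()
    return table, SceneTruth(spec=spec, parents=parents, drift=drift,
                             records=truth_records)


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------

def linear_drift(n_frames: int, rate_nm_per_frame: float) -> np.ndarray:
    t = np.arange(n_frames, dtype=float)[:, None]
    return t * np.array([rate_nm_per_frame, rate_nm_per_frame, rate_nm_per_frame])


def sinusoidal_drift(n_frames: int, amplitude_nm: float, period_frames: float) -> np.ndarray:
    t = np.arange(n_frames, dtype=float)
    s = amplitude_nm * np.sin(2 * np.pi * t / period_frames)
    return np.column_stack([s, 0.5 * s, 0.25 * s])


def generate_fiducials(
    drift_amplitude_nm: float,
    n_frames: int,
    n_beads: int,
    seed: int = 0,
    noise_nm: float = 2.0,
    drift_series: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame bead positions = true position + shared drift + noise.

    Returns the bead track table (bead, frame, x, y, z) and the shared drift
    truth (frame, dx, dy, dz).  ``drift_series`` overrides the random-walk
    drift when a specific trajectory (linear, sinusoidal, ...) is wanted.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    if drift_series is None:
        drift = _drift_series(n_frames, drift_amplitude_nm, rng)
    else:
        drift = np.asarray(drift_series, dtype=float)
        if drift.shape != (n_frames, 3):
            raise ValueError("drift_series must have shape (n_frames, 3)")
    true_pos = rng.uniform(-10000.0, 10000.0, (n_beads, 3))
    frames = np.arange(n_frames)
    recs = []
    for b in range(n_beads):
        noise = rng.normal(0.0, noise_nm, (n_frames, 3))
        pos = true_pos[b] + drift + noise
        recs.append(
            pd.DataFrame(
                {"bead": b, "frame": frames,
                 "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}
            )
        )
    beads = pd.concat(recs, ignore_index=True)
    truth = pd.DataFrame(
        {"frame": frames, "dx": drift[:, 0], "dy": drift[:, 1], "dz": drift[:, 2]}
    )
    return beads, truth


# ---------------------------------------------------------------------------
# genomic tracks
# ---------------------------------------------------------------------------

S_FRACTIONS = ("S1", "S2", "S3", "S4", "S5", "S6")
TXN_CLASSES = ("none", "low", "mid", "high")


@dataclass(frozen=True)
class GenomicTrackSpec:
    """Planted structure for synthetic coverage tracks on 10 kb bins.

    ``timing_log2_effect`` and ``txn_log2_effect`` add up to the per-bin log2
    enrichment of the sample track over input.  The expressed bins split into
    low/mid/high nascent-transcription classes at exact 10/80/10 proportions
    (choose ``n_bins`` and ``expressed_fraction`` so the counts are integral
    if exact percentile recovery matters).
    """

    n_bins: int = 600
    bin_size_bp: int = 10_000
    timing_log2_effect: tuple[float, ...] = (0.0,) * 6
    txn_log2_effect: tuple[float, ...] = (0.0,) * 4
    noise_dispersion: float = 0.0
    base_coverage: float = 20.0
    expressed_fraction: float = 0.5
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 6:
            raise ValueError("n_bins must be >= 6")
        if len(self.timing_log2_effect) != 6:
            raise ValueError("timing_log2_effect needs 6 values (S1..S6)")
        if len(self.txn_log2_effect) != 4:
            raise ValueError("txn_log2_effect needs 4 values (none/low/mid/high)")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must be in [0, 1]")


def _lognormal_noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    if sigma == 0:
        return np.ones(n)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, n))  # mean-1 multiplicative


def generate_tracks(spec: GenomicTrackSpec) -> tuple[dict, pd.DataFrame]:
    """Generate sample / input / S1-S6 / nascent bedGraph tracks.

    Returns (tracks, truth): ``tracks`` maps track name to a 4-column
    bedGraph DataFrame (chrom, start, end, value; one interval per bin), and
    ``truth`` records each bin's planted S fraction, transcription class and
    log2 enrichment effect.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    starts = np.arange(n, dtype=np.int64) * spec.bin_size_bp

    timing_idx = rng.integers(0, 6, n)

    n_expr = int(round(spec.expressed_fraction * n))
    expressed = np.zeros(n, dtype=bool)
    expressed[rng.choice(n, size=n_expr, replace=False)] = True
    txn = np.full(n, "none", dtype=object)
    nascent = np.zeros(n)
    if n_expr:
        expr_idx = rng.permutation(np.nonzero(expressed)[0])
        n_low = int(round(0.1 * n_expr))
        n_high = int(round(0.1 * n_expr))
        low_idx = expr_idx[:n_low]
        high_idx = expr_idx[n_low : n_low + n_high]
        mid_idx = expr_idx[n_low + n_high :]
        # disjoint value ranges so percentile classification recovers exactly
        nascent[low_idx] = rng.uniform(2.0, 4.0, len(low_idx))
        nascent[mid_idx] = rng.uniform(8.0, 16.0, len(mid_idx))
        nascent[high_idx] = rng.uniform(32.0, 64.0, len(high_idx))
        txn[low_idx] = "low"
        txn[mid_idx] = "mid"
        txn[high_idx] = "high"

    input_cov = spec.base_coverage * _lognormal_noise(rng, spec.noise_dispersion, n)
    timing_eff = np.asarray(spec.timing_log2_effect)[timing_idx]
    txn_eff = np.asarray(spec.txn_log2_effect)[
        [TXN_CLASSES.index(t) for t in txn]
    ]
    log2_effect = timing_eff + txn_eff
    sample_cov = input_cov * 2.0**log2_effect * _lognormal_noise(rng, spec.noise_dispersion, n)

    def bedgraph(values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": spec.chrom, "start": starts,
             "end": starts + spec.bin_size_bp, "value": values}
        )

    tracks = {"sample": bedgraph(sample_cov), "input": bedgraph(input_cov)}
    for k, frac in enumerate(S_FRACTIONS):
        cov = np.where(
            timing_idx == k, spec.base_coverage, 0.1 * spec.base_coverage
        ) * _lognormal_noise(rng, spec.noise_dispersion, n)
        tracks[frac] = bedgraph(cov)
    tracks["nascent"] = bedgraph(nascent)

    truth = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": starts,
            "s_fraction": [S_FRACTIONS[k] for k in timing_idx],
            "txn_class": txn,
            "log2_effect": log2_effect,
        }
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# pulse-chase intensities
# ---------------------------------------------------------------------------

def generate_dilution_series(
    initial_signal: float,
    n_cells: int,
    cycles,
    extra_turnover_rate: float = 0.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    cell_cycle_h: float = 24.0,
) -> pd.DataFrame:
    """Per-nucleus intensities following replication-coupled two-fold dilution
    plus optional replication-independent turnover.

    Mean intensity at c cycles = initial * 0.5**c * exp(-extra_turnover_rate*c)
    with multiplicative (mean-1, CV ``noise_cv``) gamma noise per nucleus.
    """
    if extra_turnover_rate < 0:
        raise ValueError("extra_turnover_rate must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cycles = np.atleast_1d(np.asarray(cycles, dtype=float))
    if (cycles < 0).any():
        raise ValueError("cycles must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for c in cycles:
        mean = initial_signal * 0.5**c * np.exp(-extra_turnover_rate * c)
        if noise_cv > 0:
            shape = 1.0 / noise_cv**2
            noise = rng.gamma(shape, 1.0 / shape, n_cells)
        else:
            noise = np.ones(n_cells)
        frames.append(
            pd.DataFrame(
                {
                    "nucleus_id": np.arange(n_cells),
                    "cycles": c,
                    "chase_time_h": c * cell_cycle_h,
                    "intensity": mean * noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
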
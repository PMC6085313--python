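"""Genome-wide enrichment vs replication timing vs transcription.

Coverage tracks come in as 4-column bedGraph (0-based, half-open).  The
pipeline: mean per-base coverage at consecutive 10 kb bins (depth-normalized),
log2 sample/input ratio at bins where both tracks are non-zero (smoothed over
the 5 nearest defined bins), S-phase fraction assignment by argmax over six
Repli-seq fractions, transcription classes from log2 nascent coverage
percentiles, and the (fraction x class) summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

S_FRACTIONS = ("S1", "S2", "S3", "S4", "S5", "S6")
TXN_CLASSES = ("none", "low", "mid", "high")
UNASSIGNED = "unassigned"


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def bin_coverage(
    bedgraph: pd.DataFrame,
    bin_size: int = 10_000,
    depth_normalize: bool = True,
) -> pd.DataFrame:
    """Mean per-base coverage at consecutive ``bin_size`` bins per chromosome.

    Intervals straddling bin edges contribute pro rata.  Depth normalization
    rescales values by 1e6 / total signal mass (sum of value x length), so the
    result is invariant to a common rescaling of the track.  Overlapping
    intervals within the track raise an error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    total_mass = float((bedgraph["value"] * (bedgraph["end"] - bedgraph["start"])).sum())
    scale = 1e6 / total_mass if (depth_normalize and total_mass > 0) else 1.0

    out = []
    for chrom, sub in bedgraph.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping intervals in track on {chrom}")
        values = sub["value"].to_numpy(dtype=float)
        n_bins = int(np.ceil(ends.max() / bin_size))
        acc = np.zeros(n_bins)
        for s, e, v in zip(starts, ends, values):
            b0 = s // bin_size
            b1 = (e - 1) // bin_size
            if b0 == b1:
                acc[b0] += v * (e - s)
            else:
                for b in range(b0, b1 + 1):
                    lo = max(s, b * bin_size)
                    hi = min(e, (b + 1) * bin_size)
                    acc[b] += v * (hi - lo)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_bins, dtype=np.int64) * bin_size,
                    "coverage": acc / bin_size * scale,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
    ):
        raise ValueError("bin grids do not match")


def log2_enrichment(
    sample_bins: pd.DataFrame,
    input_bins: pd.DataFrame,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """log2(sample/input) at bins where both tracks are non-zero, plus a
    series smoothed over the ``smooth_window`` nearest defined bins.

    Smoothing is a centered moving average computed on the defined bins only
    (undefined bins are skipped, chromosome ends use the available bins);
    undefined bins stay undefined (NaN).
    """
    _check_same_grid(sample_bins, input_bins)
    s = sample_bins["coverage"].to_numpy(dtype=float)
    i = input_bins["coverage"].to_numpy(dtype=float)
    defined = (s > 0) & (i > 0)
    ratio = np.full(len(s), np.nan)
    ratio[defined] = np.log2(s[defined] / i[defined])

    out = sample_bins[["chrom", "start"]].copy()
    out["log2_ratio"] = ratio
    smooth = np.full(len(s), np.nan)
    for _, idx in out.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        d = idx[defined[idx]]
        if len(d) == 0:
            continue
        vals = pd.Series(ratio[d])
        smooth[d] = vals.rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    out["log2_ratio_smooth"] = smooth
    return out


def assign_timing(repli_bins: pd.DataFrame) -> pd.Series:
    """S-phase fraction per bin = argmax coverage over S1..S6 columns.

    Ties break toward the earlier fraction; all-zero bins are unassigned.
    """
    missing = [f for f in S_FRACTIONS if f not in repli_bins.columns]
    if missing:
        raise ValueError(f"missing Repli-seq fraction column(s): {missing}")
    cov = repli_bins[list(S_FRACTIONS)].to_numpy(dtype=float)
    best = np.argmax(cov, axis=1)  # first max -> earlier fraction on ties
    labels = np.array(S_FRACTIONS, dtype=object)[best]
    labels[cov.sum(axis=1) == 0] = UNASSIGNED
    return pd.Series(labels, index=repli_bins.index, name="s_fraction")


def classify_transcription(nascent_bins: pd.DataFrame) -> pd.Series:
    """Transcription class per bin from log2-transformed nascent coverage.

    Zero-coverage bins -> none.  Among non-zero bins: <= 10th percentile ->
    low, >= 90th percentile -> high, else mid.
    """
    cov = nascent_bins["coverage"].to_numpy(dtype=float)
    nonzero = cov > 0
    if nonzero.sum() < 10:
        raise ValueError("need >= 10 non-zero bins to classify transcription")
    logs = np.log2(cov[nonzero])
    p10, p90 = np.percentile(logs, [10, 90])
    cls = np.full(len(cov), "none", dtype=object)
    nz_cls = np.where(logs <= p10, "low", np.where(logs >= p90, "high", "mid"))
    cls[nonzero] = nz_cls
    return pd.Series(cls, index=nascent_bins.index, name="txn_class")


@dataclass
class TimingSummary:
    """Mean enrichment and bin counts per S fraction and per stratum."""

    per_fraction: pd.DataFrame  # index S1..S6: mean_log2_ratio, n
    per_stratum: pd.DataFrame   # index (s_fraction, txn_class): mean_log2_ratio, n

    @property
    def n_classified(self) -> int:
        return int(self.per_stratum["n"].sum())


def summarize_by_timing(bins: pd.DataFrame) -> TimingSummary:
    """Aggregate ``log2_ratio`` by ``s_fraction`` and (fraction x txn_class).

    Bins with undefined ratio or unassigned timing are excluded.  Empty
    strata report count 0 and undefined (NaN) mean.
    """
    for col in ("log2_ratio", "s_fraction", "txn_class"):
        if col not in bins.columns:
            raise ValueError(f"bins missing column {col!r}")
    ok = bins["log2_ratio"].notna() & (bins["s_fraction"] != UNASSIGNED)
    sub = bins.loc[ok]

    frac_index = pd.CategoricalIndex(S_FRACTIONS, name="s_fraction")
    g = sub.groupby("s_fraction")["log2_ratio"]
    per_fraction = pd.DataFrame(
        {"mean_log2_ratio": g.mean(), "n": g.size()}
    ).reindex(frac_index)
    per_fraction["n"] = per_fraction["n"].fillna(0).astype(int)

    strata = pd.MultiIndex.from_product(
        [S_FRACTIONS, TXN_CLASSES], names=["s_fraction", "txn_class"]
    )
    g2 = sub.groupby(["s_fraction", "txn_class"])["log2_ratio"]
    per_stratum = pd.DataFrame(
        {"mean_log2_ratio": g2.mean(), "n": g2.size()}
    ).reindex(strata)
    per_stratum["n"] = per_stratum["n"].fillna(0).astype(int)
    return TimingSummary(per_fraction=per_fraction, per_stratum=per_stratum)


def build_bin_table(
    sample_bg: pd.DataFrame,
    input_bg: pd.DataFrame,
    repli_bgs: dict,
    nascent_bg: pd.DataFrame,
    bin_size: int = 10_000,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Full per-bin table: coverage, enrichment, timing and transcription.

    ``repli_bgs`` maps fraction names S1..S6 to bedGraph DataFrames.
    """
    sample_bins = bin_coverage(sample_bg, bin_size)
    input_bins = bin_coverage(input_bg, bin_size)
    enrich = log2_enrichment(sample_bins, input_bins, smooth_window)

    repli = enrich[["chrom", "start"]].copy()
    for frac in S_FRACTIONS:
        fb = bin_coverage(repli_bgs[frac], bin_size)
        _check_same_grid(sample_bins, fb)
        repli[frac] = fb["coverage"].to_numpy()
    nascent_bins = bin_coverage(nascent_bg, bin_size)
    _check_same_grid(sample_bins, nascent_bins)

    out = enrich.copy()
    out["sample_coverage"] = sample_bins["coverage"].to_numpy()
    out["input_coverage"] = input_bins["coverage"].to_numpy()
    out["s_fraction"] = assign_timing(repli).to_numpy()
    out["txn_class"] = classify_transcription(nascent_bins).to_numpy()
    return out
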
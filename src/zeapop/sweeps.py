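"""Turn window score tracks into discrete selective sweeps.

The calling rule follows the two-step empirical-quantile scheme: windows at
or above the 90th percentile of scores are marked and merged (overlapping or
touching marked windows form one candidate region), then regions whose best
member window strictly exceeds the 99.5th percentile are retained as
sweeps.  Nearby sweeps separated by less than 100 kb are merged into single
selected loci, and the F_ST and CLR sweep sets are combined by >=1 bp
overlap into a joint set with Venn counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end", "region_score", "n_windows"]


@dataclass
class SweepSet:
    """Non-overlapping selected regions with method/comparison provenance."""
    intervals: pd.DataFrame
    method: str = "unknown"
    comparison: str = "unknown"
    thresholds: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.intervals)

    def lengths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()


def _merge_intervals(df: pd.DataFrame, max_gap_bp: int = 0) -> pd.DataFrame:
    """Merge sorted intervals whose gap is strictly below ``max_gap_bp``
    (gap 0 = overlapping or touching); scores combine by max, counts sum."""
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    rows = []
    cur = df.iloc[0].to_dict()
    for _, r in df.iloc[1:].iterrows():
        gap = r["start"] - cur["end"]
        if r["chrom"] == cur["chrom"] and gap <= max(0, max_gap_bp - 1):
            cur["end"] = max(cur["end"], r["end"])
            cur["region_score"] = max(cur["region_score"], r["region_score"])
            cur["n_windows"] += r["n_windows"]
        else:
            rows.append(cur)
            cur = r.to_dict()
    rows.append(cur)
    out = pd.DataFrame(rows)
    out[["start", "end", "n_windows"]] = out[["start", "end", "n_windows"]].astype(np.int64)
    return out[INTERVAL_COLUMNS]


def call_sweeps(track: pd.DataFrame, merge_quantile: float = 0.90,
                outlier_quantile: float = 0.995, method: str = "unknown",
                comparison: str = "unknown", min_windows: int = 200) -> SweepSet:
    """Mark, merge, and threshold windows into putative sweeps.

    Both quantiles are computed over the window score distribution.  Windows
    scoring >= the merge quantile are merged into candidate regions
    (region score = max member window); regions whose score strictly exceeds
    the outlier quantile are retained.  When every window has the same score
    there are no strict outliers and an empty set is returned with a warning.
    """
    if len(track) < min_windows:
        raise ValueError(
            f"only {len(track)} windows; need >= {min_windows} for stable "
            "quantiles — use smaller windows or a denser step")
    scores = track["score"].to_numpy(dtype=float)
    p_mark = float(np.quantile(scores, merge_quantile))
    p_out = float(np.quantile(scores, outlier_quantile))
    marked = track.loc[scores >= p_mark,
                       ["chrom", "start", "end", "score"]].copy()
    marked = marked.rename(columns={"score": "region_score"})
    marked["n_windows"] = 1
    regions = _merge_intervals(marked[INTERVAL_COLUMNS])
    kept = regions[regions["region_score"] > p_out].reset_index(drop=True)
    if kept.empty:
        warnings.warn("no region exceeds the outlier quantile (degenerate or "
                      "flat score distribution)", UserWarning, stacklevel=2)
    return SweepSet(kept, method=method, comparison=comparison,
                    thresholds={"mark": p_mark, "outlier": p_out})


def merge_nearby(sweeps: SweepSet, max_gap_bp: int = 100_000) -> SweepSet:
    """Merge sweeps separated by a gap strictly below ``max_gap_bp``."""
    merged = _merge_intervals(sweeps.intervals, max_gap_bp=max_gap_bp)
    return SweepSet(merged, sweeps.method, sweeps.comparison, dict(sweeps.thresholds))


def _overlaps_any(df: pd.DataFrame, other: pd.DataFrame,
                  min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean per row of ``df``: overlaps >= min_overlap_bp with any in other."""
    hits = np.zeros(len(df), dtype=bool)
    for chrom, sub in other.groupby("chrom", sort=False):
        mask = (df["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in np.flatnonzero(mask):
            s, e = df["start"].iat[i], df["end"].iat[i]
            ov = np.minimum(e, ends) - np.maximum(s, starts)
            if np.any(ov >= min_overlap_bp):
                hits[i] = True
    return hits


def combine_methods(fst_sweeps: SweepSet, xpclr_sweeps: SweepSet,
                    min_overlap_bp: int = 1) -> tuple[SweepSet, dict]:
    """Union the two method sweep sets and count the Venn overlap.

    A region is "common" iff it overlaps a region from the other method by at
    least ``min_overlap_bp``.  The joint set merges overlapping regions from
    the union; the Venn counts report joint regions supported by F_ST only,
    CLR only, and by both.
    """
    if fst_sweeps.comparison != xpclr_sweeps.comparison:
        raise ValueError("sweep sets come from different comparisons")
    a = fst_sweeps.intervals.assign(_src="fst")
    b = xpclr_sweeps.intervals.assign(_src="xpclr")
    both = pd.concat([a, b], ignore_index=True)
    both = both.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    # merge union components, tracking which methods support each
    rows = []
    cur = None
    for _, r in both.iterrows():
        if cur is not None and r["chrom"] == cur["chrom"] \
                and r["start"] - cur["end"] <= -min_overlap_bp + 0:
            cur["end"] = max(cur["end"], r["end"])
            cur["region_score"] = max(cur["region_score"], r["region_score"])
            cur["n_windows"] += r["n_windows"]
            cur["_srcs"].add(r["_src"])
        else:
            if cur is not None:
                rows.append(cur)
            cur = r.to_dict()
            cur["_srcs"] = {r["_src"]}
        del_src = cur.pop("_src", None)  # noqa: F841 (column only used above)
    if cur is not None:
        rows.append(cur)
    joint = pd.DataFrame(rows)
    srcs = joint.pop("_srcs")
    venn = {
        "fst_only": int(sum(s == {"fst"} for s in srcs)),
        "xpclr_only": int(sum(s == {"xpclr"} for s in srcs)),
        "common": int(sum(len(s) == 2 for s in srcs)),
        "total": len(joint),
    }
    joint = joint[INTERVAL_COLUMNS].copy()
    joint[["start", "end", "n_windows"]] = joint[["start", "end", "n_windows"]].astype(np.int64)
    return SweepSet(joint.reset_index(drop=True), method="joint",
                    comparison=fst_sweeps.comparison), venn


def summarize_sweeps(sweeps: SweepSet, genes_bed: pd.DataFrame | None,
                     genome_sizes: dict) -> dict:
    """Count, length stats, genome coverage, and overlapped gene count."""
    if sweeps.n == 0:
        return {"n": 0, "mean_length_bp": 0.0, "min_length_bp": 0,
                "max_length_bp": 0, "genome_fraction": 0.0, "n_genes": 0}
    lengths = sweeps.lengths()
    total = float(sum(genome_sizes.values()))
    out = {
        "n": sweeps.n,
        "mean_length_bp": float(lengths.mean()),
        "min_length_bp": int(lengths.min()),
        "max_length_bp": int(lengths.max()),
        "genome_fraction": float(lengths.sum()) / total,
    }
    if genes_bed is not None:
        genes = genes_bed.sort_values(["chrom", "start"], kind="stable")
        hit = _overlaps_any(genes.reset_index(drop=True), sweeps.intervals)
        out["n_genes"] = int(hit.sum())
    else:
        out["n_genes"] = 0
    return out
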
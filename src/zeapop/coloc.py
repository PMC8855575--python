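"""Sweep / GWAS-signal co-localization and the permutation enrichment test.

A sweep is co-located with a signal catalogue entry when at least one
signal point (or interval) falls inside the sweep, optionally extended by a
flank.  Enrichment is assessed by placing the same number of regions with
the same lengths at uniformly random genomic positions (chromosome chosen
with probability proportional to its length among chromosomes that fit;
start uniform so the region fits; overlaps among placed regions are
permitted) and counting how many permuted region sets co-locate with at
least as many signals as observed.  The empirical p-value uses the
add-one correction (1 + #{perm >= obs}) / (n_perm + 1), so the smallest
achievable p at 1000 permutations is 1/1001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sweeps import SweepSet


def _signal_frame(signals: pd.DataFrame) -> pd.DataFrame:
    """Normalize a signal catalogue to half-open intervals.

    Point signals (columns ``chrom, pos``; 1-based bp) become unit intervals
    ``[pos - 1, pos)``; interval signals must carry ``chrom, start, end``.
    """
    if {"start", "end"}.issubset(signals.columns):
        return signals[["chrom", "start", "end"]].copy()
    if "pos" not in signals.columns:
        raise ValueError("signals need either pos or start/end columns")
    out = pd.DataFrame({"chrom": signals["chrom"],
                        "start": signals["pos"].astype(np.int64) - 1})
    out["end"] = out["start"] + 1
    return out


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Co-location percentage, rounded as reported (count/total * 100)."""
    return round(100.0 * count / total, ndigits)


def overlap(sweeps: SweepSet, signals: pd.DataFrame,
            flank_bp: int = 0) -> tuple[pd.DataFrame, int, float]:
    """Sweeps containing >= 1 signal within ``[start - flank, end + flank)``.

    Returns the co-located subset, its count, and the percentage of all
    sweeps (1 decimal).
    """
    sig = _signal_frame(signals)
    iv = sweeps.intervals
    hit = np.zeros(len(iv), dtype=bool)
    for chrom, sub in sig.groupby("chrom", sort=False):
        mask = (iv["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        s_start = sub["start"].to_numpy()
        s_end = sub["end"].to_numpy()
        for i in np.flatnonzero(mask):
            lo = iv["start"].iat[i] - flank_bp
            hi = iv["end"].iat[i] + flank_bp
            if np.any((s_end > lo) & (s_start < hi)):
                hit[i] = True
    subset = iv[hit].reset_index(drop=True)
    count = int(hit.sum())
    pct = percent(count, len(iv)) if len(iv) else 0.0
    return subset, count, pct


@dataclass
class EnrichmentResult:
    observed: int
    expected_mean: float
    p_value: float
    n_perm: int
    perm_counts: np.ndarray


def permutation_enrichment(sweeps: SweepSet, signals: pd.DataFrame,
                           genome_sizes: dict, n_perm: int = 1000,
                           seed: int = 0, flank_bp: int = 0) -> EnrichmentResult:
    """Permutation test of sweep/signal co-location (see module docstring)."""
    sig = _signal_frame(signals)
    lengths = sweeps.lengths().astype(np.int64)
    if lengths.size == 0:
        raise ValueError("empty sweep set")
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.max() > sizes.max():
        raise ValueError("a sweep is longer than every chromosome")

    # global concatenated coordinates make interval hit-counting a searchsorted
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    chrom_offset = {c: offsets[i] for i, c in enumerate(chroms)}
    sig_keep = sig[sig["chrom"].isin(chrom_offset)]
    if len(sig_keep):
        goff = np.array([chrom_offset[c] for c in sig_keep["chrom"]], dtype=np.int64)
        sig_starts = np.sort(sig_keep["start"].to_numpy() + goff)
        sig_ends = np.sort(sig_keep["end"].to_numpy() + goff)
    else:
        sig_starts = sig_ends = np.array([], dtype=np.int64)

    _, observed, _ = overlap(sweeps, signals, flank_bp=flank_bp)

    rng = np.random.default_rng(seed)
    m = lengths.size
    fits = sizes[None, :] >= lengths[:, None]  # (m, n_chrom)
    probs = np.where(fits, sizes[None, :], 0).astype(float)
    probs /= probs.sum(axis=1, keepdims=True)
    chrom_idx = np.empty((n_perm, m), dtype=np.int64)
    for k in range(m):
        chrom_idx[:, k] = rng.choice(len(chroms), size=n_perm, p=probs[k])
    max_start = sizes[chrom_idx] - lengths[None, :]
    starts = (rng.random((n_perm, m)) * (max_start + 1)).astype(np.int64)
    g0 = offsets[chrom_idx] + starts - flank_bp
    g1 = offsets[chrom_idx] + starts + lengths[None, :] + flank_bp
    # a signal [s0, s1) overlaps [g0, g1) iff s0 < g1 and s1 > g0; counted as
    # #{s0 < g1} - #{s1 <= g0} (the second set is contained in the first)
    n_before_end = np.searchsorted(sig_starts, g1, side="left")
    n_ended = np.searchsorted(sig_ends, g0, side="right")
    perm_counts = np.sum(n_before_end > n_ended, axis=1)

    p = (1.0 + np.sum(perm_counts >= observed)) / (n_perm + 1.0)
    return EnrichmentResult(observed=observed,
                            expected_mean=float(perm_counts.mean()),
                            p_value=float(p), n_perm=n_perm,
                            perm_counts=perm_counts)
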
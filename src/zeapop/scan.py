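"""Two-population differentiation scans: Weir–Cockerham F_ST and a
cross-population composite-likelihood-ratio (XP-CLR-style) sweep statistic.

Both statistics are evaluated on the same sliding-window grid (100 kb
windows, 10 kb step by default) so the downstream sweep sets are directly
comparable.  The F_ST estimator is the Weir & Cockerham (1984) two-allele,
two-population variance decomposition into components a (between
populations), b (between individuals within populations), and c (within
individuals); windows report the weighted ratio sum(a) / sum(a + b + c).

The composite-likelihood scan models the test-population allele frequency
at each SNP as normal around the reference frequency with drift variance
``omega * p (1 - p)``, censored to [0, 1] with the boundary mass absorbed at
the endpoints.  The sweep alternative places the selected site at the window
center: a SNP at distance d escapes with probability
``c = 1 - exp(-r d / s)`` and the density becomes the two-component
hitchhiking mixture over the background allele B in {0, 1}.  This is a
deliberately simplified plug-in-frequency variant of the XP-CLR model
(no binomial sampling layer, star-like hitchhiking), with LD-correlated SNP
clusters in the reference population down-weighted by 1 / cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_S_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)
TRACK_COLUMNS = ["chrom", "start", "end", "n_snps", "score"]


@dataclass
class FstComponents:
    """Per-SNP Weir–Cockerham variance components (arrays over SNPs)."""
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        """Per-SNP ratio a / (a + b + c); may be negative; NaN when undefined."""
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _pop_moments(dosage: np.ndarray):
    """Sample size, alt frequency, and observed het fraction per SNP."""
    called = ~np.isnan(dosage)
    n = called.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * n)
        h = np.nansum(dosage == 1.0, axis=0) / n
    return n, p, h


def wc_fst_components(dosage1: np.ndarray, dosage2: np.ndarray) -> FstComponents:
    """Weir & Cockerham (1984) a, b, c for two populations, vectorized.

    Inputs are (n_i, m) dosage matrices with NaN for missing.  SNPs with no
    called diploid in either population get NaN components (excluded from
    windows, logged by the window step).
    """
    r = 2.0
    n1, p1, h1 = _pop_moments(np.atleast_2d(dosage1))
    n2, p2, h2 = _pop_moments(np.atleast_2d(dosage2))
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = (n1 == 0) | (n2 == 0) | (nbar <= 1.0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return FstComponents(a, b, c)


def wc_fst_snp(dosage1, dosage2) -> tuple[FstComponents, float]:
    """Single-SNP convenience wrapper: components plus theta-hat."""
    comps = wc_fst_components(np.asarray(dosage1, float).reshape(-1, 1),
                              np.asarray(dosage2, float).reshape(-1, 1))
    return comps, float(comps.theta[0])


def window_grid(chrom_sizes: dict, window_bp: int = 100_000,
                step_bp: int = 10_000) -> pd.DataFrame:
    """Half-open sliding windows fully contained in each chromosome."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size - window_bp + 1, step_bp, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(s + window_bp)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def windowed_fst(variants: pd.DataFrame, comps: FstComponents,
                 chrom_sizes: dict, window_bp: int = 100_000,
                 step_bp: int = 10_000, min_snps: int = 5) -> pd.DataFrame:
    """Weighted F_ST per sliding window: sum(a) / sum(a + b + c).

    SNPs with NaN components (missing in one population) are excluded;
    windows with fewer than ``min_snps`` remaining SNPs are dropped.
    """
    valid = np.isfinite(comps.a) & np.isfinite(comps.b) & np.isfinite(comps.c)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.info("windowed_fst: excluding %d SNPs without valid components",
                    n_dropped)
    rows = []
    for chrom, size in chrom_sizes.items():
        on = (variants["chrom"] == chrom).to_numpy() & valid
        pos = variants.loc[on, "pos"].to_numpy() - 1  # to 0-based bp
        a = comps.a[on]
        abc = a + comps.b[on] + comps.c[on]
        order = np.argsort(pos)
        pos, a, abc = pos[order], a[order], abc[order]
        ca = np.concatenate([[0.0], np.cumsum(a)])
        cabc = np.concatenate([[0.0], np.cumsum(abc)])
        starts = np.arange(0, size - window_bp + 1, step_bp, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        n_in = hi - lo
        num = ca[hi] - ca[lo]
        den = cabc[hi] - cabc[lo]
        keep = n_in >= min_snps
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(den != 0, num / den, 0.0)
        for s, n_w, sc in zip(starts[keep], n_in[keep], score[keep]):
            rows.append((chrom, int(s), int(s + window_bp), int(n_w), float(sc)))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def global_fst(dosage1: np.ndarray, dosage2: np.ndarray) -> float:
    """Genome-wide weighted Weir–Cockerham ratio over all valid SNPs."""
    comps = wc_fst_components(dosage1, dosage2)
    valid = np.isfinite(comps.a)
    num = np.nansum(comps.a[valid])
    den = np.nansum(comps.a[valid] + comps.b[valid] + comps.c[valid])
    return float(num / den)


def pairwise_global_fst(gm: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Symmetric matrix of genome-wide weighted F_ST between all groups."""
    labels = groups.reindex(gm.samples)
    names = [g for g in labels.unique() if pd.notna(g)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, g1 in enumerate(names):
        d1 = gm.dosage[(labels == g1).to_numpy()]
        for g2 in names[i + 1:]:
            d2 = gm.dosage[(labels == g2).to_numpy()]
            f = global_fst(d1, d2)
            out.loc[g1, g2] = out.loc[g2, g1] = f
    return out


# ---------------------------------------------------------------------------
# XP-CLR-style composite likelihood
# ---------------------------------------------------------------------------

def estimate_omega(ref_freqs: np.ndarray, test_freqs: np.ndarray,
                   min_snps: int = 100) -> float:
    """Drift scale: mean of (p_test - p_ref)^2 / (p_ref (1 - p_ref)).

    Restricted to SNPs with reference frequency strictly inside
    (0.05, 0.95); under Balding–Nichols drift E[omega-hat] = F.
    """
    ref = np.asarray(ref_freqs, float)
    test = np.asarray(test_freqs, float)
    mask = np.isfinite(ref) & np.isfinite(test) & (ref > 0.05) & (ref < 0.95)
    if mask.sum() < min_snps:
        raise ValueError(f"only {int(mask.sum())} informative SNPs "
                         f"(need >= {min_snps}) to estimate omega")
    r = ref[mask]
    return float(np.mean((test[mask] - r) ** 2 / (r * (1.0 - r))))


def _censored_normal_logpdf(x, mu, var):
    """log density of N(mu, var) censored to [0, 1].

    Interior points use the normal pdf; observations at exactly 0 or 1 get
    the absorbed boundary mass.
    """
    sd = np.sqrt(var)
    z = (x - mu) / sd
    interior = -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi * var)
    at0 = log_ndtr((0.0 - mu) / sd)
    at1 = log_ndtr(-(1.0 - mu) / sd)
    out = np.where(x <= 0.0, at0, np.where(x >= 1.0, at1, interior))
    return out


def _clr_batch(p_ref, p_test, dist, omega, recomb_rate_per_bp, s_grid, weights):
    """Vectorized CLR over a batch of windows.

    All inputs are (W, k) arrays (k SNPs per window).  Returns (W,) scores.
    """
    v = omega * p_ref * (1.0 - p_ref)  # (W, k)
    log_null = _censored_normal_logpdf(p_test, p_ref, v)
    null_sum = np.sum(weights * log_null, axis=1)  # (W,)
    best = np.full(p_ref.shape[0], -np.inf)
    for s in s_grid:
        c = 1.0 - np.exp(-recomb_rate_per_bp * dist / s)  # (W, k)
        mu1 = c * p_ref + (1.0 - c)  # background allele B = 1
        mu0 = c * p_ref              # background allele B = 0
        with np.errstate(divide="ignore"):
            la = np.log(p_ref) + _censored_normal_logpdf(p_test, mu1, v)
            lb = np.log1p(-p_ref) + _censored_normal_logpdf(p_test, mu0, v)
        log_alt = logsumexp(np.stack([la, lb]), axis=0)
        best = np.maximum(best, np.sum(weights * log_alt, axis=1))
    return np.maximum(2.0 * (best - null_sum), 0.0)


def _ld_weights(ref_dosage: np.ndarray, ld_r2_cap: float) -> np.ndarray:
    """1 / cluster-size weights from reference-population r^2 among k SNPs."""
    X = ref_dosage.astype(np.float64)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    R = (X / sd).T @ (X / sd) / X.shape[0]
    r2 = R**2
    k = r2.shape[0]
    adj = r2 > ld_r2_cap
    # connected components of the correlated-SNP graph (k <= 5)
    comp = -np.ones(k, dtype=int)
    for i in range(k):
        if comp[i] >= 0:
            continue
        stack, comp[i] = [i], i
        while stack:
            u = stack.pop()
            for w in np.flatnonzero(adj[u]):
                if comp[w] < 0:
                    comp[w] = i
                    stack.append(w)
    sizes = np.array([(comp == comp[i]).sum() for i in range(k)], dtype=float)
    return 1.0 / sizes


def xpclr_window(p_ref, p_test, positions, center, omega,
                 recomb_rate_per_bp: float = 1e-8, s_grid=DEFAULT_S_GRID,
                 weights=None) -> float:
    """Composite likelihood ratio for one window with the sweep at ``center``.

    ``p_ref``/``p_test`` are per-SNP allele frequencies; SNPs with degenerate
    reference frequency (0 or 1) must be excluded beforehand.  ``weights``
    default to 1 per SNP (supply LD-cluster weights for the full model).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    p_ref = np.atleast_2d(np.asarray(p_ref, float))
    p_test = np.atleast_2d(np.asarray(p_test, float))
    if np.any((p_ref <= 0) | (p_ref >= 1)):
        raise ValueError("degenerate reference frequencies must be excluded")
    dist = np.abs(np.atleast_2d(np.asarray(positions, float)) - center)
    w = np.ones_like(p_ref) if weights is None else np.atleast_2d(
        np.asarray(weights, float))
    return float(_clr_batch(p_ref, p_test, dist, omega, recomb_rate_per_bp,
                            s_grid, w)[0])


def xpclr_scan(variants: pd.DataFrame, ref_freqs: np.ndarray,
               test_freqs: np.ndarray, chrom_sizes: dict,
               ref_dosage: np.ndarray | None = None,
               window_bp: int = 100_000, step_bp: int = 10_000,
               n_snps_per_window: int = 5, omega: float | None = None,
               recomb_rate_per_bp: float = 1e-8, s_grid=DEFAULT_S_GRID,
               ld_r2_cap: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Genome-wide sliding-window CLR scan on the shared window grid.

    Exactly ``n_snps_per_window`` SNPs are scored per window (a seeded
    uniform subsample when more are eligible; the window is skipped when
    fewer), mirroring fixed min/max SNP settings.  Eligible SNPs have finite
    frequencies in both populations and non-degenerate reference frequency.
    ``omega`` is estimated from the genome-wide frequencies when not given.
    Passing ``ref_dosage`` (samples x SNPs, aligned with ``variants``)
    enables 1/cluster-size LD down-weighting in the reference population.
    """
    ref = np.asarray(ref_freqs, float)
    test = np.asarray(test_freqs, float)
    if omega is None:
        omega = estimate_omega(ref, test)
    if omega <= 0:
        raise ValueError("omega must be > 0")
    eligible = np.isfinite(ref) & np.isfinite(test) & (ref > 0) & (ref < 1)
    rng = np.random.default_rng(seed)
    k = n_snps_per_window

    sel_rows, sel_idx = [], []
    for chrom, size in chrom_sizes.items():
        on = (variants["chrom"] == chrom).to_numpy() & eligible
        idx = np.flatnonzero(on)
        pos = variants.loc[on, "pos"].to_numpy() - 1
        order = np.argsort(pos)
        pos, idx = pos[order], idx[order]
        starts = np.arange(0, size - window_bp + 1, step_bp, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        for s, l, h in zip(starts, lo, hi):
            if h - l < k:
                continue
            members = idx[l:h]
            if members.size > k:
                members = np.sort(rng.choice(members, size=k, replace=False))
            sel_rows.append((chrom, int(s), int(s + window_bp)))
            sel_idx.append(members)
    if not sel_rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)

    sel_idx = np.array(sel_idx)  # (W, k)
    pos_all = variants["pos"].to_numpy() - 1
    P_ref = ref[sel_idx]
    P_test = test[sel_idx]
    centers = np.array([(s + e) / 2.0 for _, s, e in sel_rows])
    D = np.abs(pos_all[sel_idx] - centers[:, None])
    if ref_dosage is not None:
        W = np.empty_like(P_ref)
        for wi in range(sel_idx.shape[0]):
            W[wi] = _ld_weights(ref_dosage[:, sel_idx[wi]], ld_r2_cap)
    else:
        W = np.ones_like(P_ref)
    scores = _clr_batch(P_ref, P_test, D, omega, recomb_rate_per_bp, s_grid, W)
    track = pd.DataFrame(sel_rows, columns=["chrom", "start", "end"])
    track["n_snps"] = k
    track["score"] = scores
    return track[TRACK_COLUMNS]
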
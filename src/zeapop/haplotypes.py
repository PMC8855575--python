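"""Window-based haplotype analysis on phased genotypes.

The genome is tiled into 50-kb windows; within each window at most five SNPs
(a seeded random subset when more are present, the same subset for every
individual) define a short haplotype, and each distinct haplotype string is
treated as an allele at that locus.  On top of this catalog sit per-group
haplotype counts, rarefaction richness, group-specific haplotypes, the
shared-ancestry categories of maize haplotypes (MPM/MM/PM/M), and a
sample-size-equalizing bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

MISSING = -1


def build_loci(variants: pd.DataFrame, window_bp: int = 50_000,
               max_snps: int = 5, seed: int = 0) -> pd.DataFrame:
    """Tile each chromosome into non-overlapping windows and pick SNP subsets.

    Windows with no SNPs are dropped; windows with more than ``max_snps``
    SNPs get a seeded uniform random subset of exactly ``max_snps`` (indices
    kept in ascending position).  Returns a DataFrame with columns
    ``chrom, start, end, snp_indices`` (half-open bp intervals).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        win = (pos - 1) // window_bp  # 1-based pos -> half-open window bin
        for w in np.unique(win):
            members = idx[win == w]
            if members.size > max_snps:
                members = np.sort(rng.choice(members, size=max_snps, replace=False))
            rows.append((chrom, int(w) * window_bp, (int(w) + 1) * window_bp,
                         members))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_indices"])


@dataclass
class HaplotypeCatalog:
    """Per-locus haplotype codes for every sample's two phased gametes.

    ``codes`` has shape (n_loci, n_samples, 2); each entry encodes the
    haplotype string over the locus' SNP subset as an integer in
    ``[0, 2**n_snps)``, or -1 when any constituent allele is missing.
    """
    loci: pd.DataFrame
    codes: np.ndarray
    samples: list
    groups: pd.Series

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def group_mask(self, group) -> np.ndarray:
        labels = self.groups.reindex(self.samples)
        if isinstance(group, str):
            mask = (labels == group).to_numpy()
        else:
            mask = labels.isin(list(group)).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return mask

    def group_haplotypes(self, group) -> np.ndarray:
        """Haplotype codes of a group, shape (n_loci, 2 * n_group_samples)."""
        mask = self.group_mask(group)
        sub = self.codes[:, mask, :]
        return sub.reshape(self.n_loci, -1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format catalog (``chrom start end allele group count``)."""
        recs = []
        for li in range(self.n_loci):
            row = self.loci.iloc[li]
            for g in self.groups.unique():
                haps = self.group_haplotypes(g)[li]
                haps = haps[haps != MISSING]
                vals, counts = np.unique(haps, return_counts=True)
                for v, c in zip(vals, counts):
                    recs.append((row.chrom, row.start, row.end, int(v), g, int(c)))
        return pd.DataFrame(recs, columns=["chrom", "start", "end",
                                           "allele", "group", "count"])


def call_haplotypes(gm: GenotypeMatrix, loci: pd.DataFrame,
                    groups: pd.Series) -> HaplotypeCatalog:
    """Encode each sample's two phased haplotypes at every locus.

    Haplotypes containing a missing allele at any locus SNP are excluded
    (coded -1) and their number logged.
    """
    if gm.haplotypes is None:
        raise ValueError("genotypes are unphased: phase them or use the "
                         "simulator, which emits truth haplotypes")
    n = gm.n_samples
    codes = np.empty((len(loci), n, 2), dtype=np.int16)
    n_missing = 0
    for li, members in enumerate(loci["snp_indices"]):
        sub = gm.haplotypes[:, members, :]  # (n, k, 2)
        weights = (1 << np.arange(len(members)))[None, :, None]
        code = (sub * weights).sum(axis=1)
        bad = np.any(sub == MISSING, axis=1)
        code[bad] = MISSING
        n_missing += int(bad.sum())
        codes[li] = code
    if n_missing:
        logger.info("call_haplotypes: excluded %d haplotypes with missing alleles",
                    n_missing)
    return HaplotypeCatalog(loci.reset_index(drop=True), codes,
                            list(gm.samples), groups)


def _distinct_per_row(a: np.ndarray) -> np.ndarray:
    """Distinct non-missing values per row of a 2-D integer array."""
    s = np.sort(a, axis=1)
    valid = s != MISSING
    new = np.ones(s.shape, dtype=bool)
    new[:, 1:] = s[:, 1:] != s[:, :-1]
    return np.sum(valid & new, axis=1)


def haplotype_summary(catalog: HaplotypeCatalog, groups_of_interest,
                      rarefaction_g: int | None = None) -> pd.DataFrame:
    """Table-style per-group summary of the window-haplotype catalog."""
    rows = []
    spec = group_specific(catalog, groups_of_interest)
    for g in groups_of_interest:
        haps = catalog.group_haplotypes(g)
        per_locus = _distinct_per_row(haps)
        n_samp = int(catalog.group_mask(g).sum())
        row = {"group": g, "sample_size": n_samp,
               "n_haplotypes": int(per_locus.sum()),
               "n_per_locus": float(per_locus.mean()),
               "n_specific": int(spec.loc[g, "n_specific"]),
               "n_specific_per_line": float(spec.loc[g, "n_specific"]) / n_samp}
        if rarefaction_g is not None:
            row["richness"] = float(np.mean(richness(catalog, rarefaction_g,
                                                     groups=[g])[g]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _rarefied_locus(counts: np.ndarray, g: int) -> float:
    """Expected distinct alleles in a subsample of g haplotypes.

    ``sum_i [1 - C(N - N_i, g) / C(N, g)]`` with N the total haplotypes
    sampled at the locus and N_i each allele's count.
    """
    N = counts.sum()
    # log C(n, k) via gammaln; C(n, k) = 0 when n < k
    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = N - counts
    with np.errstate(invalid="ignore"):
        ratio = np.where(rest >= g, np.exp(logC(rest, g) - logC(N, g)), 0.0)
    return float(np.sum(1.0 - ratio))


def richness(catalog: HaplotypeCatalog, g: int, groups=None) -> dict:
    """Per-group, per-locus rarefied haplotype richness at subsample size g.

    Raises (naming the limiting group) if g exceeds the number of non-missing
    haplotypes of any group at any locus.
    """
    if groups is None:
        groups = list(catalog.groups.unique())
    out = {}
    for grp in groups:
        haps = catalog.group_haplotypes(grp)
        n_valid = np.sum(haps != MISSING, axis=1)
        if np.any(n_valid < g):
            raise ValueError(
                f"rarefaction size g={g} exceeds the sampled haplotypes of "
                f"group {grp!r} at {int(np.sum(n_valid < g))} loci "
                f"(minimum {int(n_valid.min())})")
        vals = np.empty(catalog.n_loci)
        for li in range(catalog.n_loci):
            row = haps[li]
            _, counts = np.unique(row[row != MISSING], return_counts=True)
            vals[li] = _rarefied_locus(counts, g)
        out[grp] = vals
    return out


def _presence_table(catalog: HaplotypeCatalog, groups) -> dict:
    """For each group, a per-locus list of the set of observed codes."""
    table = {}
    for grp in groups:
        haps = catalog.group_haplotypes(grp)
        table[grp] = [set(row[row != MISSING].tolist()) for row in haps]
    return table


def group_specific(catalog: HaplotypeCatalog, comparison_groups) -> pd.DataFrame:
    """Haplotypes observed in exactly one of the comparison groups.

    A haplotype allele (per locus) is specific to a group iff its count is
    positive there and zero in every other comparison group.
    """
    comparison_groups = list(comparison_groups)
    if len(comparison_groups) < 2:
        raise ValueError("need at least 2 comparison groups")
    pres = _presence_table(catalog, comparison_groups)
    counts = {g: 0 for g in comparison_groups}
    for li in range(catalog.n_loci):
        sets = {g: pres[g][li] for g in comparison_groups}
        for g in comparison_groups:
            others = set().union(*(sets[h] for h in comparison_groups if h != g))
            counts[g] += len(sets[g] - others)
    df = pd.DataFrame({"n_specific": pd.Series(counts)})
    df.index.name = "group"
    return df


MAIZE_SUBSETS = {"all": ("tropical", "temperate"),
                 "tropical": ("tropical",), "temperate": ("temperate",)}


def shared_categories(catalog: HaplotypeCatalog, maize_subset="all",
                      mexicana_group: str = "mexicana",
                      parviglumis_group: str = "parviglumis") -> dict:
    """Classify every maize-observed haplotype by teosinte sharing.

    Categories partition the distinct haplotypes observed in the chosen
    maize subset: MPM (also in mexicana AND parviglumis), MM (mexicana
    only), PM (parviglumis only), M (maize-private).  Returns percentages
    summing to 100.
    """
    if isinstance(maize_subset, str):
        try:
            maize_groups = MAIZE_SUBSETS[maize_subset]
        except KeyError:
            raise KeyError(f"maize_subset must be one of {list(MAIZE_SUBSETS)}")
    else:
        maize_groups = tuple(maize_subset)
    groups = list(maize_groups) + [mexicana_group, parviglumis_group]
    pres = _presence_table(catalog, groups)
    tallies = {"MPM": 0, "MM": 0, "PM": 0, "M": 0}
    for li in range(catalog.n_loci):
        maize = set().union(*(pres[g][li] for g in maize_groups))
        mex = pres[mexicana_group][li]
        par = pres[parviglumis_group][li]
        for h in maize:
            in_mex, in_par = h in mex, h in par
            if in_mex and in_par:
                tallies["MPM"] += 1
            elif in_mex:
                tallies["MM"] += 1
            elif in_par:
                tallies["PM"] += 1
            else:
                tallies["M"] += 1
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no maize haplotypes observed")
    return {k: 100.0 * v / total for k, v in tallies.items()}


def bootstrap_equalize(catalog: HaplotypeCatalog, n: int = 75, reps: int = 100,
                       seed: int = 0, replace: bool = False,
                       groups=None) -> pd.DataFrame:
    """Equalize group sample sizes by repeated subsampling and recount.

    Per replicate and group, ``n`` samples are drawn (without replacement by
    default; a group with <= n samples is used whole, logged) and the mean
    per-locus number of distinct haplotypes is recomputed.  Returns a
    (reps x groups) DataFrame with a stable group column order.
    """
    if groups is None:
        groups = list(dict.fromkeys(catalog.groups.reindex(catalog.samples))).copy()
    rng = np.random.default_rng(seed)
    out = np.empty((reps, len(groups)))
    for gi, grp in enumerate(groups):
        rows = np.flatnonzero(catalog.group_mask(grp))
        whole = (not replace) and rows.size <= n
        if whole and rows.size < n:
            logger.info("group %s has %d < n=%d samples; using whole group",
                        grp, rows.size, n)
        for r in range(reps):
            if whole:
                pick = rows
            else:
                pick = rng.choice(rows, size=n, replace=replace)
            haps = catalog.codes[:, pick, :].reshape(catalog.n_loci, -1)
            out[r, gi] = _distinct_per_row(haps).mean()
    return pd.DataFrame(out, columns=list(groups))
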
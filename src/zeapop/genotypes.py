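"""Genotype containers, VCF I/O, QC filters, and per-SNP statistics.

The central object is :class:`GenotypeMatrix`, a samples x SNPs allele-dosage
matrix ({0, 1, 2}, NaN for missing) with an optional pair of phased haplotype
sequences per sample.  Variant metadata (chromosome, 1-based position, alleles)
travels alongside as a pandas DataFrame; positions are strictly increasing
within each chromosome.  All window coordinates used downstream are half-open
``[start, end)`` in bp, while VCF positions stay 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeMatrix:
    """Samples x biallelic-SNPs dosage matrix with optional phased haplotypes.

    Parameters
    ----------
    samples : sequence of str
        Ordered sample identifiers.
    variants : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``; positions
        1-based and strictly increasing within each chromosome.
    dosage : ndarray of shape (n_samples, n_snps)
        Alternate-allele counts in {0, 1, 2}; ``NaN`` marks missing calls.
    haplotypes : ndarray of shape (n_samples, n_snps, 2), optional
        Phased alleles in {0, 1}; ``-1`` marks missing.  When present, the
        haplotype sum must equal the dosage at every non-missing entry.
    """

    def __init__(self, samples, variants: pd.DataFrame, dosage: np.ndarray,
                 haplotypes: np.ndarray | None = None):
        self.samples = list(samples)
        self.variants = variants.reset_index(drop=True)
        self.dosage = np.asarray(dosage, dtype=np.float32)
        self.haplotypes = None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"dosage has {n} rows but {len(self.samples)} samples")
        if m != len(self.variants):
            raise ValueError(f"dosage has {m} columns but {len(self.variants)} variants")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (n, m, 2):
                raise ValueError("haplotypes shape must be (n_samples, n_snps, 2)")
            hap_ok = np.all(self.haplotypes >= 0, axis=2)
            dose_ok = ~np.isnan(self.dosage)
            both = hap_ok & dose_ok
            if not np.array_equal(self.haplotypes[both].reshape(-1, 2).sum(axis=1),
                                  self.dosage[both].astype(np.int64)):
                raise ValueError("haplotype sums disagree with dosage")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def take_snps(self, index) -> "GenotypeMatrix":
        """Subset SNPs by integer index or boolean mask (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        haps = None if self.haplotypes is None else self.haplotypes[:, index, :]
        return GenotypeMatrix(self.samples, self.variants.iloc[index],
                              self.dosage[:, index], haps)

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        samples = [self.samples[i] for i in index]
        haps = None if self.haplotypes is None else self.haplotypes[index]
        return GenotypeMatrix(samples, self.variants, self.dosage[index], haps)

    def copy(self) -> "GenotypeMatrix":
        haps = None if self.haplotypes is None else self.haplotypes.copy()
        return GenotypeMatrix(list(self.samples), self.variants.copy(),
                              self.dosage.copy(), haps)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a :class:`GenotypeMatrix` plus its variant table.

    Only biallelic SNP records are kept; others are skipped with a logged
    count.  Phased genotypes (``|`` separator) populate the haplotype array;
    any unphased or half-missing record leaves haplotypes at ``-1`` there, and
    a file with no phased entries at all yields ``haplotypes=None``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages, haps = [], [], []
    n_skipped = 0
    any_phased = False
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = np.array(var.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        a = g[:, :2].astype(np.float32)
        a[a < 0] = np.nan
        dose = a.sum(axis=1)
        h = g[:, :2].astype(np.int8)
        h[np.any(g[:, :2] < 0, axis=1)] = -1
        # unphased heterozygotes carry no phase information
        unphased = (g[:, 2] == 0) & (h[:, 0] != h[:, 1])
        h[unphased] = -1
        if np.any(g[:, 2] == 1):
            any_phased = True
        rows.append((var.CHROM, var.POS, var.ID or f"snp{i}", var.REF, var.ALT[0]))
        dosages.append(dose)
        haps.append(h)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.array(dosages, dtype=np.float32).T if dosages else np.empty((len(samples), 0), np.float32)
    hap_arr = None
    if any_phased and haps:
        hap_arr = np.stack(haps, axis=1)  # (n_samples, n_snps, 2)
        # keep haplotypes consistent with dosage: half-calls already masked
        missing = np.isnan(dosage)
        hap_arr[missing] = -1
    gm = GenotypeMatrix(samples, variants, dosage, hap_arr)
    gm.n_skipped_records = n_skipped
    return gm, gm.variants


def write_vcf(gm: GenotypeMatrix, path, chrom_sizes: dict | None = None) -> None:
    """Write a minimal VCFv4.2 file; phased GT (``a|b``) when haplotypes exist."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zeapop\n")
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={int(size)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        phased = gm.haplotypes is not None
        for j in range(gm.n_snps):
            v = gm.variants.iloc[j]
            fields = [str(v.chrom), str(int(v.pos)), str(v.id), v.ref, v.alt,
                      ".", "PASS", ".", "GT"]
            if phased:
                col = gm.haplotypes[:, j, :]
                gts = [f"{a}|{b}" if a >= 0 and b >= 0 else "./." for a, b in col]
            else:
                col = gm.dosage[:, j]
                lut = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                gts = ["./." if np.isnan(d) else lut[float(d)] for d in col]
            fh.write("\t".join(fields + gts) + "\n")


def read_groups(path) -> pd.Series:
    """Read a ``sample<TAB>group`` TSV into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "group"]:
        df.columns = ["sample", "group"] + list(df.columns[2:])
    return df.set_index("sample")["group"]


def write_groups(groups: pd.Series, path) -> None:
    groups.rename_axis("sample").rename("group").reset_index().to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and per-SNP statistics
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of SNPs removed by each QC criterion (a SNP can fail several)."""
    n_input: int = 0
    n_retained: int = 0
    n_missing: int = 0
    n_monomorphic: int = 0
    n_maf: int = 0
    removed: dict = field(default_factory=dict)


def filter_snps(gm: GenotypeMatrix, max_missing: float = 0.20,
                require_polymorphic: bool = True,
                min_maf: float = 0.0) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP QC rules: missingness, polymorphism, and MAF.

    Retains SNPs with a missing fraction strictly below ``max_missing``, with
    both alleles observed when ``require_polymorphic``, and with MAF at least
    ``min_maf``.  SNP order is preserved and the report counts removals per
    criterion.
    """
    miss_frac = np.mean(np.isnan(gm.dosage), axis=0)
    keep = miss_frac < max_missing
    rep = FilterReport(n_input=gm.n_snps)
    rep.n_missing = int(np.sum(~keep))

    p = allele_freq(gm)
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1)
    if require_polymorphic:
        rep.n_monomorphic = int(np.sum(keep & ~np.nan_to_num(poly, nan=False)))
        keep &= np.nan_to_num(poly, nan=False)
    if min_maf > 0:
        mafs = np.minimum(p, 1 - p)
        ok = np.nan_to_num(mafs, nan=-1.0) >= min_maf
        rep.n_maf = int(np.sum(keep & ~ok))
        keep &= ok
    rep.n_retained = int(keep.sum())
    if rep.n_retained == 0:
        warnings.warn("filter_snps removed every SNP", UserWarning, stacklevel=2)
    return gm.take_snps(keep), rep


def allele_freq(gm: GenotypeMatrix, groups: pd.Series | None = None,
                group: str | None = None) -> np.ndarray:
    """Alternate-allele frequency per SNP, optionally within one sample group.

    Frequencies are taken over non-missing alleles; a SNP with no data in the
    group returns NaN.  Note that for fully inbred lines the denominator is
    2n alleles but only n independent gametes.
    """
    dose = gm.dosage
    if group is not None:
        if groups is None:
            raise ValueError("groups must be given when group is requested")
        labels = groups.reindex(gm.samples)
        mask = (labels == group).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown or empty group {group!r}")
        dose = dose[mask]
    n_called = np.sum(~np.isnan(dose), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dose, axis=0) / (2.0 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    if np.any(n_called == 0):
        logger.info("allele_freq: %d SNPs with no data in selection",
                    int(np.sum(n_called == 0)))
    return freq


def maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per SNP (NaN where no calls)."""
    p = allele_freq(gm)
    return np.minimum(p, 1 - p)


def pic(freqs) -> np.ndarray | float:
    """Polymorphic information content from allele frequencies.

    ``PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``.  For biallelic SNPs
    given as a scalar/1-D array of alternate-allele frequencies ``p`` this is
    ``1 - p^2 - q^2 - 2 p^2 q^2``.  A 1-D input of length K summing to 1 is
    interpreted as one K-allele frequency vector.
    """
    arr = np.asarray(freqs, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if arr.ndim == 1 and arr.size > 1 and np.isclose(arr.sum(), 1.0):
        p2 = arr ** 2
        cross = (p2.sum() ** 2 - np.sum(p2 ** 2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
        return float(1.0 - p2.sum() - 2.0 * cross)
    q = 1.0 - arr
    out = 1.0 - arr**2 - q**2 - 2.0 * arr**2 * q**2
    return float(out) if np.isscalar(freqs) else out


def snp_stats_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP summary (``chrom pos maf pic``) as written to the stats TSV."""
    p = allele_freq(gm)
    return pd.DataFrame({
        "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"],
        "maf": np.minimum(p, 1 - p),
        "pic": pic(p),
    })
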
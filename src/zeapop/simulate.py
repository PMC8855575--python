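"""Synthetic four-population Zea-like cohorts with known truth.

The generator emulates the hierarchy of a maize/teosinte diversity panel:
two outbred teosinte-like populations (*parviglumis*, *mexicana*) and two
fully inbred maize-like populations (tropical, temperate).  Allele
frequencies start from a truncated Beta at the root of a fixed population
tree and drift along each edge under the Balding–Nichols model,

    p_child ~ Beta(p (1-F)/F, (1-p)(1-F)/F),

so that E[p_child] = p and Var[p_child] = F p (1-p).  The tree topology is
fixed to the inferred Zea lineage: (parviglumis, mexicana) split at the
root, the maize ancestor branches off the parviglumis lineage, and the
temperate population derives from the tropical one.  SNPs are drawn
independently (no background LD); linkage structure arises only through
shared drift and planted sweeps.

Sweeps are planted with the same star-like hitchhiking model the scan
assumes: a SNP at distance d from the sweep center escapes with probability
``c = 1 - exp(-r d / s)`` and otherwise is dragged to the single hitchhiking
background allele B.  This deliberate generator/analysis coupling makes
parameter-recovery tests well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, write_vcf, write_groups

OUTBRED = "outbred_HWE"
INBRED = "fully_inbred"
DEFAULT_RECOMB_RATE = 1e-8  # per bp; 1 cM/Mb


@dataclass(frozen=True)
class PopulationSpec:
    """One population: sample size, mating system, and drift on its edge."""
    name: str
    n_samples: int
    ploidy_model: str = OUTBRED
    drift_F: float = 0.1

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError(f"{self.name}: n_samples must be >= 2")
        if not 0 < self.drift_F < 1:
            raise ValueError(f"{self.name}: drift_F must lie in (0, 1)")
        if self.ploidy_model not in (OUTBRED, INBRED):
            raise ValueError(f"{self.name}: unknown ploidy_model {self.ploidy_model!r}")


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep in one target population."""
    target_population: str
    chrom: str
    center: int
    half_width: int
    s_tilde: float

    def __post_init__(self):
        if self.s_tilde <= 0:
            raise ValueError("s_tilde must be > 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


@dataclass(frozen=True)
class TraitModel:
    """Additive trait: causal SNP effects plus polygenic and noise terms."""
    causal_snps: tuple
    effects: tuple
    h2_polygenic: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if len(self.causal_snps) != len(self.effects):
            raise ValueError("causal_snps and effects must have equal length")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must lie in [0, 1)")


# Edge drift defaults: chosen once so pairwise FST lands roughly in the
# 0.10-0.21 band typical of maize/teosinte subgroups and cumulative drift
# orders haplotype diversity parviglumis > mexicana > tropical > temperate.
def default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("parviglumis", 75, OUTBRED, 0.05),
        PopulationSpec("mexicana", 96, OUTBRED, 0.14),
        PopulationSpec("tropical", 120, INBRED, 0.06),
        PopulationSpec("temperate", 100, INBRED, 0.15),
    ]


TREE_ORDER = ("parviglumis", "mexicana", "tropical", "temperate")
TEOSINTE = ("parviglumis", "mexicana")
MAIZE = ("tropical", "temperate")


@dataclass
class Cohort:
    """A simulated cohort: genotypes, group labels, truth frequencies."""
    gm: GenotypeMatrix
    groups: pd.Series
    chrom_sizes: dict
    pop_freqs: dict = field(default_factory=dict)
    pop_specs: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    sweeps: list = field(default_factory=list)

    def copy(self) -> "Cohort":
        return Cohort(self.gm.copy(), self.groups.copy(), dict(self.chrom_sizes),
                      {k: v.copy() for k, v in self.pop_freqs.items()},
                      dict(self.pop_specs), self.missing_rate, list(self.sweeps))


def _truncated_beta(rng, a, b, lo, hi, size):
    """Beta(a, b) restricted to [lo, hi] via inverse-CDF sampling."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def _balding_nichols(rng, p, F):
    # clip: a Beta draw can round to exactly 0/1, which would make the
    # next level's shape parameters degenerate
    p = np.clip(p, 1e-9, 1 - 1e-9)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def _draw_haplotypes(rng, freqs, n, model):
    m = freqs.size
    if model == INBRED:
        h = (rng.random((n, 1, m)) < freqs).astype(np.int8)
        return np.repeat(h, 2, axis=1)
    return (rng.random((n, 2, m)) < freqs).astype(np.int8)


def simulate_cohort(pop_specs=None, n_chrom: int = 10,
                    chrom_length_bp: int = 20_000_000, n_snps: int = 40_000,
                    missing_rate: float = 0.05, seed: int = 0,
                    beta_shape: tuple = (0.8, 0.8),
                    freq_bounds: tuple = (0.05, 0.95),
                    parviglumis_stem_F: float = 0.03,
                    maize_ancestor_F: float = 0.12) -> Cohort:
    """Simulate a four-population cohort on a multi-chromosome genome.

    ``pop_specs`` must contain exactly the four populations named in
    ``TREE_ORDER`` (any order).  ``parviglumis_stem_F`` is the drift between
    the root and the point where the maize ancestor attaches to the
    parviglumis lineage; ``maize_ancestor_F`` is the drift on the maize-stem
    edge itself.

    Returns a :class:`Cohort` whose genotype matrix carries phased haplotypes
    (outbred samples draw two gametes per SNP; inbred samples draw one gamete
    and duplicate it, so heterozygosity is exactly zero before masking).
    """
    if not 0 <= missing_rate <= 0.2:
        raise ValueError("missing_rate must lie in [0, 0.2]")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if pop_specs is None:
        pop_specs = default_populations()
    specs = {s.name: s for s in pop_specs}
    if set(specs) != set(TREE_ORDER):
        raise ValueError(f"pop_specs must name exactly {TREE_ORDER}")
    for F in (parviglumis_stem_F, maize_ancestor_F):
        if not 0 < F < 1:
            raise ValueError("stem drift values must lie in (0, 1)")

    rng = np.random.default_rng(seed)

    # genome: near-equal SNP counts per chromosome, unique sorted positions
    chrom_sizes = {f"chr{i + 1}": chrom_length_bp for i in range(n_chrom)}
    counts = np.full(n_chrom, n_snps // n_chrom)
    counts[: n_snps % n_chrom] += 1
    rows = []
    for (chrom, size), k in zip(chrom_sizes.items(), counts):
        pos = np.sort(rng.choice(np.arange(1, size + 1), size=k, replace=False))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    variants = pd.concat(rows, ignore_index=True)
    variants["id"] = [f"S{c[3:]}_{p}" for c, p in zip(variants.chrom, variants.pos)]
    variants["ref"] = "A"
    variants["alt"] = "T"
    variants = variants[["chrom", "pos", "id", "ref", "alt"]]

    # frequencies down the fixed tree
    p_root = _truncated_beta(rng, beta_shape[0], beta_shape[1],
                             freq_bounds[0], freq_bounds[1], n_snps)
    p_node = _balding_nichols(rng, p_root, parviglumis_stem_F)
    freqs = {
        "parviglumis": _balding_nichols(rng, p_node, specs["parviglumis"].drift_F),
        "mexicana": _balding_nichols(rng, p_root, specs["mexicana"].drift_F),
    }
    p_maize_anc = _balding_nichols(rng, p_node, maize_ancestor_F)
    freqs["tropical"] = _balding_nichols(rng, p_maize_anc, specs["tropical"].drift_F)
    freqs["temperate"] = _balding_nichols(rng, freqs["tropical"], specs["temperate"].drift_F)

    samples, labels, hap_blocks = [], [], []
    for name in TREE_ORDER:
        spec = specs[name]
        hap_blocks.append(_draw_haplotypes(rng, freqs[name], spec.n_samples,
                                           spec.ploidy_model))
        samples += [f"{name[:4]}_{i:04d}" for i in range(spec.n_samples)]
        labels += [name] * spec.n_samples
    haplotypes = np.concatenate(hap_blocks, axis=0)  # (n, 2, m)
    dosage = haplotypes.sum(axis=1).astype(np.float32)

    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate  # (n, m)
        dosage[mask] = np.nan
        haplotypes[np.broadcast_to(mask[:, None, :], haplotypes.shape)] = -1
    haplotypes = np.transpose(haplotypes, (0, 2, 1))  # (n, m, 2)

    gm = GenotypeMatrix(samples, variants, dosage, haplotypes)
    groups = pd.Series(labels, index=samples, name="group")
    return Cohort(gm, groups, chrom_sizes, freqs, specs, missing_rate)


def plant_sweep(cohort: Cohort, sweep: SweepSpec,
                recomb_rate_per_bp: float = DEFAULT_RECOMB_RATE,
                seed: int = 0) -> Cohort:
    """Overwrite target-population frequencies with a hitchhiking sweep.

    Each SNP within ``center +/- half_width`` escapes the sweep with
    probability ``c = 1 - exp(-r d / s_tilde)``; its population frequency
    becomes ``c p + (1 - c) B`` where B is one per-sweep draw of the
    hitchhiking background allele (B = 1 with probability p at the center
    SNP).  Target-population haplotypes at affected SNPs are redrawn from the
    new frequencies; the existing missingness pattern is preserved.
    """
    if sweep.target_population not in cohort.pop_specs:
        raise KeyError(f"unknown target population {sweep.target_population!r}")
    if sweep.chrom not in cohort.chrom_sizes:
        raise ValueError(f"sweep chromosome {sweep.chrom!r} not in genome")
    size = cohort.chrom_sizes[sweep.chrom]
    if sweep.center - sweep.half_width < 0 or sweep.center + sweep.half_width > size:
        raise ValueError("sweep interval extends outside the chromosome")

    out = cohort.copy()
    rng = np.random.default_rng(seed)
    var = out.gm.variants
    on_chrom = (var["chrom"] == sweep.chrom).to_numpy()
    d = np.abs(var["pos"].to_numpy() - sweep.center)
    affected = np.flatnonzero(on_chrom & (d <= sweep.half_width))
    if affected.size == 0:
        raise ValueError("no SNPs fall inside the sweep interval")

    name = sweep.target_population
    p = out.pop_freqs[name]
    center_idx = affected[np.argmin(d[affected])]
    B = float(rng.random() < p[center_idx])
    c = 1.0 - np.exp(-recomb_rate_per_bp * d[affected] / sweep.s_tilde)
    p_new = p.copy()
    p_new[affected] = c * p[affected] + (1 - c) * B
    out.pop_freqs[name] = p_new

    spec = out.pop_specs[name]
    rows = np.flatnonzero((out.groups == name).to_numpy())
    new_h = _draw_haplotypes(rng, p_new[affected], rows.size, spec.ploidy_model)
    new_h = np.transpose(new_h, (0, 2, 1))  # (n, m_aff, 2)
    sub = out.gm.haplotypes[np.ix_(rows, affected)]
    was_missing = np.all(sub < 0, axis=2)
    new_h[was_missing] = -1
    out.gm.haplotypes[np.ix_(rows, affected)] = new_h
    dose = new_h.sum(axis=2).astype(np.float32)
    dose[was_missing] = np.nan
    out.gm.dosage[np.ix_(rows, affected)] = dose
    out.sweeps.append(replace(sweep))
    return out


def simulate_phenotype(cohort: Cohort, trait: TraitModel, seed: int = 0,
                       name: str = "trait") -> pd.DataFrame:
    """Simulate an additive quantitative trait for every sample.

    ``y = sum_k effect_k * dosage_k + g + e`` where the polygenic term g has
    covariance proportional to the realized kinship matrix, scaled so that
    ``var(g) / (var(g) + var(e)) = h2_polygenic``, and e is i.i.d.
    ``N(0, noise_sd^2)``.  Missing causal dosages are mean-imputed.
    """
    gm = cohort.gm
    for k in trait.causal_snps:
        if not 0 <= k < gm.n_snps:
            raise IndexError(f"causal SNP index {k} out of range")
    rng = np.random.default_rng(seed)
    y = np.zeros(gm.n_samples)
    for k, eff in zip(trait.causal_snps, trait.effects):
        x = gm.dosage[:, k].astype(float)
        mu = np.nanmean(x)
        x = np.where(np.isnan(x), mu, x)
        y += eff * x
    if trait.h2_polygenic > 0 and trait.noise_sd > 0:
        from .gwas import kinship
        K, _ = kinship(gm)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(K.shape[0]))
        g0 = L @ rng.standard_normal(K.shape[0])
        var_g = trait.h2_polygenic / (1 - trait.h2_polygenic) * trait.noise_sd**2
        sd0 = g0.std()
        if sd0 > 0:
            y += g0 * np.sqrt(var_g) / sd0
    if trait.noise_sd > 0:
        y += rng.normal(0.0, trait.noise_sd, size=gm.n_samples)
    return pd.DataFrame({"sample": gm.samples, "trait": name, "value": y})


def random_gene_bed(chrom_sizes: dict, n_genes: int = 200,
                    gene_length_bp: int = 4000, seed: int = 0) -> pd.DataFrame:
    """Random non-overlapping gene intervals (BED3+name, sorted)."""
    rng = np.random.default_rng(seed)
    total = sum(chrom_sizes.values())
    rows = []
    counter = 0
    for chrom, size in chrom_sizes.items():
        k = max(1, round(n_genes * size / total))
        # lay genes on a jittered grid so they can never overlap
        slots = np.linspace(0, size - gene_length_bp, num=max(k, 1)).astype(np.int64)
        jitter = rng.integers(0, max(1, (size // max(k, 1)) - gene_length_bp),
                              size=slots.size)
        starts = np.minimum(slots + jitter, size - gene_length_bp)
        starts = np.unique(starts)
        for s in starts:
            rows.append((chrom, int(s), int(s + gene_length_bp), f"gene{counter:05d}"))
            counter += 1
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return bed.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_cohort(cohort: Cohort, out_dir, trait: TraitModel | None = None,
                 phenotype: pd.DataFrame | None = None, n_genes: int = 200,
                 gene_length_bp: int = 4000, seed: int = 0) -> dict:
    """Write the cohort to plain-text files; returns the paths.

    Emits a phased VCF, sample-group TSV, a random non-overlapping gene BED,
    a GWAS-signal TSV with the causal SNP positions (when a trait model is
    given), and a phenotype TSV (when provided).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "cohort.vcf", "groups": out / "samples.tsv",
             "genes": out / "genes.bed"}
    write_vcf(cohort.gm, paths["vcf"], cohort.chrom_sizes)
    write_groups(cohort.groups, paths["groups"])
    bed = random_gene_bed(cohort.chrom_sizes, n_genes, gene_length_bp, seed)
    bed.to_csv(paths["genes"], sep="\t", index=False, header=False)
    if trait is not None:
        sig = cohort.gm.variants.iloc[list(trait.causal_snps)][["chrom", "pos"]].copy()
        sig["trait"] = "trait"
        paths["signals"] = out / "signals.tsv"
        sig.to_csv(paths["signals"], sep="\t", index=False)
    if phenotype is not None:
        paths["phenotype"] = out / "phenotype.tsv"
        phenotype.to_csv(paths["phenotype"], sep="\t", index=False)
    return paths
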
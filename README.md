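# zeapop

Population-genomic scans for crop domestication and adaptation, modelled on
the maize/teosinte study design: a diversity panel of outbred wild relatives
(*Zea mays* ssp. *parviglumis* and ssp. *mexicana*) and fully inbred
cultivated lines (tropical and temperate pools) genotyped at tens of
thousands of biallelic SNPs.  The package takes phased genotypes from a VCF
(or generates a fully synthetic cohort with known truth) and carries them
through the complete analysis chain:

1. **QC and per-SNP statistics** — missingness/polymorphism/MAF filters,
   allele frequencies, polymorphic information content (PIC).
2. **Structure** — PCA on a standardized genomic relationship matrix,
   identity-by-state distances, a neighbor-joining tree rooted on an
   outgroup, and the membership-probability rule (≥ 0.70, else "Mix") that
   turns a Q-matrix into group labels.
3. **Window haplotypes** — 50-kb loci with at most five SNPs each, haplotype
   alleles per group, rarefaction richness, group-specific haplotypes, the
   MPM/MM/PM/M teosinte-sharing categories, and a 75-sample × 100-replicate
   equalizing bootstrap.
4. **Selection scans** — Weir–Cockerham F_ST (weighted Σa/Σ(a+b+c)) and an
   XP-CLR-style composite likelihood ratio, both on 100-kb windows sliding
   by 10 kb with at least/exactly five SNPs per window.
5. **Sweep calling** — merge adjacent windows at the top-10% mark, retain
   top-0.5% outlier regions, fuse sweeps separated by < 100 kb, and combine
   the two methods by ≥ 1 bp overlap.
6. **Co-localization** — overlap of sweeps with GWAS-signal catalogues or
   known genes, with a 1000-permutation enrichment test (random region sets
   of identical number and sizes).
7. **GWAS** — PLINK-style LD pruning, Bonferroni threshold 1/M, a
   P3D/EMMAX-style mixed linear model (`y = Xb + u + e`,
   `u ~ N(0, σ_g² K)`) with kinship and PC covariates, locus resolution,
   and per-group allele-frequency contrasts at lead SNPs.

The statistics at the core are the two-population Weir–Cockerham variance
components

    θ̂(window) = Σ_snps a / Σ_snps (a + b + c),

and a composite likelihood ratio in which the test-population frequency at a
SNP at distance *d* from a putative sweep site escapes the sweep with
probability `c = 1 − exp(−r d / s̃)` and otherwise is dragged to a single
hitchhiking background allele; the CLR maximizes over a grid of sweep
strengths `s̃` and is floored at 0 (see `docs/methods.md`).

## Worked example

```python
import numpy as np, pandas as pd
from zeapop import simulate as sim
from zeapop.genotypes import allele_freq
from zeapop.scan import wc_fst_components, windowed_fst, xpclr_scan
from zeapop.sweeps import call_sweeps, merge_nearby, combine_methods

cohort = sim.simulate_cohort(n_snps=40_000, seed=7)    # 10 x 20 Mb genome
cohort = sim.plant_sweep(cohort, sim.SweepSpec(
    "temperate", "chr1", 3_000_000, 300_000, s_tilde=0.05), seed=1)

labels = cohort.groups.reindex(cohort.gm.samples)
trop = cohort.gm.dosage[(labels == "tropical").to_numpy()]
temp = cohort.gm.dosage[(labels == "temperate").to_numpy()]

comps = wc_fst_components(trop, temp)
ftrack = windowed_fst(cohort.gm.variants, comps, cohort.chrom_sizes)
fst_sweeps = merge_nearby(call_sweeps(ftrack, method="fst",
                                      comparison="adaptation"))
print(fst_sweeps.intervals.head())
```

prints (seed 7) a sweep table whose first region covers the planted interval
on chr1:

```
  chrom     start       end  region_score  n_windows
0  chr1   2620000   3390000      0.790898         68
1  chr2  10280000  10470000      0.257472          9
2  chr4   9180000   9410000      0.204590         13
3  chr5   7140000   7400000      0.240412         17
4  chr5  16160000  16350000      0.250994         10
```

`region_score` is the best member-window weighted F_ST, and the chr1 region
(2.62–3.39 Mb) brackets the planted sweep center at 3.0 Mb; the remaining
small regions are the background empirical-quantile outliers.  The same track
grid feeds `xpclr_scan`, and `combine_methods` reports Venn counts of
F_ST-only / CLR-only / common regions.

A `zeapop` console script exposes the same steps
(`simulate`, `scan`, `call-sweeps`, `coloc`, `gwas`); see `zeapop --help`.

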
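# Methods

This note records the models, the defaults that matter, and the design
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator emulates a four-population *Zea*-like diversity panel.
Ancestral allele frequencies are drawn from Beta(0.8, 0.8) truncated to
[0.05, 0.95] (truncation keeps drift from fixing too many sites), and drift
along each edge of a fixed population tree follows the Balding–Nichols
model `p_child ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so E[p_child] = p and
Var = F·p(1−p).  The topology is hard-coded to the inferred *Zea* lineage:
*parviglumis* and *mexicana* split at the root; the maize ancestor branches
off the *parviglumis* lineage (the stem drift before the attachment point is
`parviglumis_stem_F`, default 0.03, and the maize-stem drift is
`maize_ancestor_F`, default 0.12); temperate maize derives from the tropical
population.

Default edge drift values (population `drift_F`): parviglumis 0.05,
mexicana 0.14, tropical 0.06, temperate 0.15.  They were chosen once so
that (i) pairwise Weir–Cockerham F_ST between the four groups lands roughly
in the 0.10–0.21 band reported for maize/teosinte subgroups, with
teosinte–maize pairs high and tropical–temperate lowest, and (ii)
cumulative drift orders expected haplotype diversity
parviglumis > mexicana > tropical > temperate.  Default sample sizes
(75 / 96 / 120 / 100) keep the teosinte groups at realistic panel sizes and
exceed the 75-sample equalizing bootstrap.

Teosinte-like populations are outbred (two gametes drawn independently per
SNP, Hardy–Weinberg within the population); maize-like populations are
fully inbred (one gamete drawn and duplicated, heterozygosity exactly zero
before masking).  Genotypes are masked missing uniformly at random
(default rate 0.05, capped at 0.20 to match the QC regime the filters
expect).

**What the generator does not emulate.**  SNPs are drawn independently:
there is no background linkage disequilibrium, no recombination map, no
ascertainment bias, and no genotyping-error structure.  LD arises only
through shared drift and planted sweeps.  Consequently, per-locus haplotype
counts are higher than array data would give (50-kb windows in real maize
data are far more haplotype-poor), and LD-based down-weighting in the CLR
scan is exercised only by sweep-induced correlation.  Passing tests
demonstrate internal correctness and parameter recovery under this model,
not performance on real arrays.

### Planted sweeps

A sweep in population P at center x₀ with strength `s̃` replaces the
population frequency of each SNP at distance d ≤ `half_width` by
`c·p + (1−c)·B`, where `c = 1 − exp(−r·d/s̃)` is the escape probability
(r = recombination rate, default 1e-8 per bp = 1 cM/Mb) and B ∈ {0, 1} is a
single per-sweep draw of the hitchhiking background allele (B = 1 with
probability p at the center SNP).  Haplotypes are redrawn from the new
frequencies; the missingness pattern is preserved.  This transform
deliberately matches the scan's alternative model so composite-likelihood
parameter recovery is a well-posed test — a coupling to keep in mind when
interpreting CLR power results.

### Phenotypes

`y = Σ_k effect_k·dosage_k + g + e` with `g` multivariate normal with
covariance proportional to the realized standardized kinship matrix, scaled
so `var(g)/(var(g)+var(e)) = h2_polygenic`, and `e ~ N(0, noise_sd²)`.
Missing causal dosages are mean-imputed.

## Per-SNP statistics

PIC uses the PowerMarker definition
`1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` (for biallelic SNPs
`1 − p² − q² − 2p²q²`).  The source analyses do not print their formula;
this standard definition is adopted and plain observed allele frequencies
are used.  Coordinates are 1-based inclusive in VCFs and half-open
`[start, end)` bp for all internal windows.

## Structure tools

PCA standardizes genotypes by `(x − 2p)/sqrt(2p(1−p))` after per-SNP mean
imputation of missing calls (zero-variance SNPs excluded); coordinates are
eigenvectors of the relationship matrix scaled by the square root of their
eigenvalues.  IBS distances use pairwise-complete SNPs (mean imputation for
PCA, pairwise deletion for IBS, matching common tool behaviour).  Neighbor
joining delegates to scikit-bio's Saitou–Nei implementation with negative
branch lengths clamped to zero; outgroup rooting bisects the outgroup's
pendant edge.  The Q-matrix assignment rule is: label = the cluster with
membership ≥ 0.70 (inclusive boundary; the largest wins if several clusters
pass a low threshold, ties to the lowest column index), otherwise "Mix".
Model-based clustering itself (ADMIXTURE) is treated as an input, not
reimplemented: the assignment rule, not the clustering algorithm, is what
the pipeline standardizes.

## Window haplotypes

The genome is tiled into non-overlapping 50-kb windows; windows with more
than five SNPs get one seeded uniform subset of exactly five, used for all
individuals, so every locus carries one to five SNPs.  Haplotypes with any
missing constituent allele are excluded from counts rather than imputed (no
phasing-quality model is available).  Inbred lines contribute both (equal)
gametes by default, configurable by subsetting.  Rarefaction richness is
the standard hypergeometric form `Σ_i [1 − C(N−N_i, g)/C(N, g)]`.  Note:
under this definition richness can never exceed the observed mean count for
g ≤ sample size, whereas published summary tables in this study design
report richness values slightly above the per-locus mean; the discrepancy
is inherent to whatever non-standard estimator produced those tables, and
this package intentionally implements the standard form.  The equalizing
bootstrap subsamples n = 75 samples per group without replacement
(a "bootstrap" of samples that reads as subsampling; a with-replacement
switch exists); a group at or below n is used whole.  Group-specific
haplotypes are evaluated against the explicitly supplied comparison set
only.

## Selection scans

F_ST uses the Weir & Cockerham (1984) two-population estimator; windows
report the weighted ratio `Σa / Σ(a+b+c)` over member SNPs (not the mean of
per-SNP ratios), windows with fewer than five informative SNPs are dropped,
and negative window values are kept so empirical quantiles are unbiased.

The composite-likelihood scan is a documented simplification of the
XP-CLR model: reference frequencies are plugged in (no binomial sampling
layer), the null for the test frequency is `N(p_ref, ω·p_ref(1−p_ref))`
censored to [0, 1] with boundary mass absorbed at the endpoints, and the
sweep alternative at the window center is the star-like hitchhiking mixture
`p_ref·N(c p_ref + (1−c), ωv) + (1−p_ref)·N(c p_ref, ωv)`.  The drift
scale ω is the mean of `(p_test − p_ref)²/(p_ref(1−p_ref))` over SNPs with
reference frequency in (0.05, 0.95) — under Balding–Nichols drift its
expectation is F.  Exactly five SNPs are scored per window (seeded
subsample when more are eligible; the window is skipped when fewer);
reference-population SNP clusters with r² > 0.95 are down-weighted by
1/cluster-size; `CLR = 2·[max_{s̃} Σ w log f_alt − Σ w log f_null]` over the
grid s̃ ∈ {0.001, 0.005, 0.01, 0.05, 0.1}, floored at 0 (the s̃ → 0 limit
reproduces the null).  The sweep site is fixed at the window center, and
the reference population defaults to teosinte (domestication) or tropical
maize (adaptation), both configurable.

## Sweep calling

Both quantiles are computed on the window score distribution: windows
scoring at or above the 90th percentile are marked and merged
(overlapping or touching windows form one candidate region, region score =
best member window), then regions strictly above the 99.5th percentile are
retained.  The strict outlier cut is deliberate: it makes the degenerate
all-equal-scores track yield an empty sweep set instead of flagging the
whole genome, and with continuous scores the two conventions agree.
Sweeps separated by < 100 kb (strict) merge into single loci.  Two method
sets combine by ≥ 1 bp overlap (configurable); the joint set is the merged
union, with Venn counts of single- and double-support regions.

## Co-localization

A sweep is co-located with a catalogue entry when ≥ 1 signal point (or
interval) intersects `[start − flank, end + flank)`.  The permutation null
places the same number of regions with the same lengths at uniformly random
positions — chromosome chosen with probability proportional to length among
chromosomes that fit, start uniform so the region fits, overlaps among
placed regions permitted (a rejection-sampling non-overlap variant was
considered and rejected as immaterial at the sweep densities involved).
The statistic counts co-located sweeps (not hit signals), and
`p = (1 + #{perm ≥ obs})/(n_perm + 1)`, so the smallest achievable p at
1000 permutations is 1/1001 ≈ 0.000999.

## GWAS

LD pruning follows the PLINK block scheme (window 50 SNPs, step 50,
r² ≥ 0.2 removes the later SNP of a pair).  The Bonferroni cutoff is 1/M on
the pruned count.  The mixed model estimates variance components once on
the null model by REML over the ratio δ = σ_e²/σ_g² (eigendecomposition of
K, 21-point log-grid bracketing plus bounded 1-D minimization), then tests
each SNP by generalized least squares with δ fixed — the P3D/EMMAX
approximation, chosen over per-SNP REML for desk-scale speed.  The default
test statistic is an F on the residual degrees of freedom, which reduces
*exactly* to the ordinary-least-squares F test when K = I; a Wald
chi-square option exists.  Covariates default to the first three genotype
PCs; kinship is the same standardized relationship matrix as the PCA and is
eigenvalue-clamped if numerically non-PSD.  Significant SNPs within 1 Mb
(configurable; the true locus-merging rule behind published counts is
unstated, so this default is an explicit assumption) merge into loci led by
the minimum-p SNP.  Group allele-frequency contrasts count inbred
heterozygotes as 0.5 and log their presence.

## Problem sizes used in the checks

The test suite runs everything on synthetic data sized for a desktop: the
sweep-recovery experiment uses ten replicates of a 10 × 20 Mb genome with
40,000 SNPs, five planted sweeps (s̃ = 0.05, half-width 300 kb) and
50 + 50 inbred test/reference samples; null calibrations use 200 replicates
of 1000 permutations and a 5000-SNP association panel; the haplotype
ordering check uses a 20,000-SNP, 10-chromosome cohort at the default
sample sizes.  These sizes were chosen as the smallest at which the
quantile machinery (top 0.5% of ~20,000 windows) and the rank statistics
are stable.

## Known limitations

- No background LD implies XP-CLR's LD weighting is rarely engaged by
  neutral data; real arrays would engage it constantly.
- The CLR model and the sweep generator share the escape-probability form;
  power estimates are internal-consistency checks, not field performance.
- Only biallelic SNPs are supported end to end; multiallelic records are
  skipped at VCF ingest.
- Statistical phasing is out of scope; the pipeline requires phased input
  (the simulator emits truth phase).
- The mixed model fits one variance ratio for all SNPs (P3D); strongly
  structured traits can deviate from per-SNP REML results.
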
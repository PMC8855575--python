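"""Mixed-linear-model association scan with kinship and structure control.

The model is ``y = X b + Z u + e`` with polygenic effect
``u ~ N(0, sigma_g^2 K)`` and ``e ~ N(0, sigma_e^2 I)``.  Variance
components are estimated once on the null (no-SNP) model by restricted
maximum likelihood over the variance ratio ``delta = sigma_e^2 / sigma_g^2``
after an eigendecomposition of K (the EMMA rotation); every SNP is then
tested by generalized least squares with the ratio held fixed — the
population-parameters-previously-determined (P3D/EMMAX) scheme.  The
default per-SNP test is an F test on the residual degrees of freedom, which
reduces exactly to the ordinary-least-squares F test when K is the
identity; a Wald chi-square option is available.

Also here: PLINK-style block LD pruning, the Bonferroni cutoff 1/M on the
pruned SNP count, merging significant SNPs into loci, and per-group allele
frequency contrasts at a chosen SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, allele_freq

logger = logging.getLogger(__name__)


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 50,
             r2_threshold: float = 0.2) -> np.ndarray:
    """Greedy block LD pruning; returns indices of retained SNPs.

    Within each block of ``window_snps`` consecutive SNPs (advancing by
    ``step_snps``), the later-positioned SNP of any pair with
    r^2 >= threshold against an already-kept SNP is removed.  Pairwise r^2
    uses pairwise-complete observations.
    """
    m = gm.n_snps
    removed = np.zeros(m, dtype=bool)
    X = gm.dosage.astype(np.float64)
    for block_start in range(0, m, step_snps):
        block = np.arange(block_start, min(block_start + window_snps, m))
        block = block[~removed[block]]
        if block.size < 2:
            continue
        sub = X[:, block]
        kept: list[int] = []
        for j in range(block.size):
            xj = sub[:, j]
            drop = False
            for i in kept:
                xi = sub[:, i]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() < 3:
                    continue
                vi, vj = xi[ok], xj[ok]
                si, sj = vi.std(), vj.std()
                if si == 0 or sj == 0:
                    continue
                r = np.mean((vi - vi.mean()) * (vj - vj.mean())) / (si * sj)
                if r * r >= r2_threshold:
                    drop = True
                    break
            if drop:
                removed[block[j]] = True
            else:
                kept.append(j)
    return np.flatnonzero(~removed)


def bonferroni_threshold(m_independent: int) -> float:
    """Genome-wide significance cutoff 1/M for M independent tests."""
    if m_independent < 1:
        raise ValueError("need at least one independent test")
    return 1.0 / m_independent


def kinship(gm: GenotypeMatrix) -> tuple[np.ndarray, list]:
    """Standardized-genotype relationship matrix (VanRaden-style).

    Same construction as the PCA relationship matrix: genotypes centered by
    2p, scaled by sqrt(2p(1-p)), cross-product over SNPs / n_SNPs.
    """
    from .structure import grm
    return grm(gm), list(gm.samples)


@dataclass
class AssociationResult:
    """Per-SNP effects, tests and p-values from an association scan."""
    table: pd.DataFrame
    trait: str = "trait"
    n_samples: int = 0
    variance_ratio: float = np.nan
    sigma_g2: float = np.nan
    sigma_e2: float = np.nan


def _reml_delta(yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 on the null model."""
    n, q = Xt.shape

    def neg2_reml(log_delta: float) -> float:
        d = lam + np.exp(log_delta)
        Xd = Xt / d[:, None]
        A = Xt.T @ Xd
        sign, logdet_A = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, Xd.T @ yt)
        r = yt - Xt @ beta
        ssr = r @ (r / d)
        return (n - q) * np.log(ssr) + np.sum(np.log(d)) + logdet_A

    grid = np.linspace(-10.0, 10.0, 21)
    vals = [neg2_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    return float(np.exp(res.x))


def _repair_psd(K: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(K)
    if evals.min() >= -1e-8:
        return K
    logger.info("kinship not PSD (min eigenvalue %.3g); clamping", evals.min())
    evals = np.maximum(evals, 0.0)
    return (evecs * evals) @ evecs.T


def mlm_scan(gm: GenotypeMatrix, phenotype: pd.Series,
             kinship_matrix: np.ndarray | None = None,
             covariates: int | np.ndarray | None = 3,
             min_maf: float = 0.05, stat: str = "f",
             trait: str = "trait") -> AssociationResult:
    """P3D mixed-linear-model scan of every SNP against one phenotype.

    Parameters
    ----------
    phenotype : Series indexed by sample ID; samples with missing phenotype
        are dropped.
    kinship_matrix : precomputed K aligned with ``gm.samples``; computed from
        the genotypes when None.
    covariates : number of leading genotype PCs to include (int), an explicit
        (n x c) array, or None for intercept only.
    min_maf : SNPs below this MAF (among analyzed samples) are not tested.
    stat : "f" (default; exact OLS reduction when K = I) or "wald".
    """
    pheno = phenotype.reindex(gm.samples)
    keep = pheno.notna().to_numpy()
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples with phenotype")
    sub = gm.take_samples(keep) if not keep.all() else gm
    y = pheno[keep].to_numpy(dtype=float)
    n = sub.n_samples

    if kinship_matrix is None:
        K, _ = kinship(sub)
    else:
        K = np.asarray(kinship_matrix, dtype=float)
        if K.shape[0] == gm.n_samples and not keep.all():
            K = K[np.ix_(keep, keep)]
    K = _repair_psd(K)

    if covariates is None:
        C = np.empty((n, 0))
    elif isinstance(covariates, (int, np.integer)):
        if covariates == 0:
            C = np.empty((n, 0))
        else:
            from .structure import grm_pca
            C = grm_pca(sub, n_components=int(covariates))[0].to_numpy()
    else:
        C = np.asarray(covariates, dtype=float)
        if C.shape[0] == gm.n_samples and not keep.all():
            C = C[keep]
    X0 = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("covariates are singular with the intercept")

    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    X0t = U.T @ X0
    delta = _reml_delta(yt, X0t, lam)
    d = lam + delta
    q0 = X0.shape[1]
    # null variance components (REML)
    Xd = X0t / d[:, None]
    beta0 = np.linalg.solve(X0t.T @ Xd, Xd.T @ yt)
    r0 = yt - X0t @ beta0
    sigma_g2 = float(r0 @ (r0 / d) / (n - q0))
    sigma_e2 = float(sigma_g2 * delta)

    # frequencies and MAF filter on the analyzed samples
    p = allele_freq(sub)
    mafs = np.minimum(p, 1 - p)
    testable = np.flatnonzero(np.nan_to_num(mafs, nan=-1.0) >= min_maf)

    dose = sub.dosage.astype(np.float64)
    mu = np.nanmean(dose, axis=0)
    dose = np.where(np.isnan(dose), mu, dose)
    Gt = U.T @ dose[:, testable]  # rotate all tested SNPs at once

    q = q0 + 1
    df_resid = n - q
    inv_d = 1.0 / d
    A00 = X0t.T @ (X0t * inv_d[:, None])
    b0 = X0t.T @ (yt * inv_d)
    yty = yt @ (yt * inv_d)

    eff = np.full(testable.size, np.nan)
    se = np.full(testable.size, np.nan)
    fstat = np.full(testable.size, np.nan)
    for j in range(testable.size):
        x = Gt[:, j]
        xd = x * inv_d
        A = np.empty((q, q))
        A[:q0, :q0] = A00
        A[:q0, q0] = A[q0, :q0] = X0t.T @ xd
        A[q0, q0] = x @ xd
        b = np.concatenate([b0, [x @ (yt * inv_d)]])
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ b
        ssr = yty - beta @ b
        s2 = ssr / df_resid
        var_b = s2 * Ainv[q0, q0]
        if var_b <= 0:
            continue
        eff[j] = beta[q0]
        se[j] = np.sqrt(var_b)
        fstat[j] = beta[q0] ** 2 / var_b
    if stat == "f":
        pvals = stats.f.sf(fstat, 1, df_resid)
    elif stat == "wald":
        pvals = stats.chi2.sf(fstat, 1)
    else:
        raise ValueError("stat must be 'f' or 'wald'")

    tab = sub.variants.iloc[testable][["chrom", "pos", "id", "ref", "alt"]].copy()
    tab["maf"] = mafs[testable]
    tab["effect"] = eff
    tab["se"] = se
    tab["stat"] = fstat
    tab["p"] = pvals
    tab = tab.reset_index(drop=True)
    return AssociationResult(tab, trait=trait, n_samples=n,
                             variance_ratio=delta, sigma_g2=sigma_g2,
                             sigma_e2=sigma_e2)


def resolve_loci(result: AssociationResult, cutoff: float,
                 merge_distance_bp: int = 1_000_000) -> pd.DataFrame:
    """Merge significant SNPs within ``merge_distance_bp`` into loci.

    Returns one row per locus with the lead SNP (minimum p), its position,
    alleles, MAF and p-value, plus the SNP count and span of the locus.
    """
    tab = result.table
    sig = tab[tab["p"] <= cutoff].sort_values(["chrom", "pos"], kind="stable")
    if sig.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps",
                                     "lead_id", "lead_pos", "ref", "alt",
                                     "maf", "p"])
    rows = []
    cur: list = []
    prev_chrom, prev_pos = None, None
    for _, r in sig.iterrows():
        if cur and (r["chrom"] != prev_chrom
                    or r["pos"] - prev_pos > merge_distance_bp):
            rows.append(cur)
            cur = []
        cur.append(r)
        prev_chrom, prev_pos = r["chrom"], r["pos"]
    rows.append(cur)
    out = []
    for members in rows:
        sub = pd.DataFrame(members)
        lead = sub.loc[sub["p"].idxmin()]
        out.append({"chrom": lead["chrom"], "start": int(sub["pos"].min()),
                    "end": int(sub["pos"].max()) + 1, "n_snps": len(sub),
                    "lead_id": lead["id"], "lead_pos": int(lead["pos"]),
                    "ref": lead["ref"], "alt": lead["alt"],
                    "maf": float(lead["maf"]), "p": float(lead["p"])})
    return pd.DataFrame(out)


def group_freq_contrast(gm: GenotypeMatrix, groups: pd.Series, snp,
                        allele: str) -> pd.Series:
    """Frequency of ``allele`` at one SNP in each sample group.

    For inbred panels this is the fraction of lines homozygous for the
    allele; heterozygotes count 0.5 and are logged.  Groups with no
    non-missing call return NaN.
    """
    if isinstance(snp, str):
        matches = np.flatnonzero((gm.variants["id"] == snp).to_numpy())
        if matches.size == 0:
            raise KeyError(f"SNP {snp!r} not found")
        j = int(matches[0])
    else:
        j = int(snp)
    v = gm.variants.iloc[j]
    if allele == v["alt"]:
        dose = gm.dosage[:, j] / 2.0
    elif allele == v["ref"]:
        dose = 1.0 - gm.dosage[:, j] / 2.0
    else:
        raise ValueError(f"allele {allele!r} not present at SNP {v['id']}")
    n_het = int(np.nansum(gm.dosage[:, j] == 1.0))
    if n_het:
        logger.info("group_freq_contrast: %d heterozygous calls counted 0.5",
                    n_het)
    labels = groups.reindex(gm.samples)
    out = {}
    for g in labels.dropna().unique():
        vals = dose[(labels == g).to_numpy()]
        vals = vals[~np.isnan(vals)]
        out[g] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(out, name=f"freq_{allele}")
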
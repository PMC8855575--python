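"""LD pruning, kinship, the mixed-model scan, and locus resolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zeapop import simulate as sim
from zeapop.genotypes import filter_snps
from zeapop.gwas import (AssociationResult, bonferroni_threshold,
                         group_freq_contrast, kinship, ld_prune, mlm_scan,
                         resolve_loci)

from conftest import make_gm


def ols_oracle(y, x, covariates=None):
    """Independent ordinary-least-squares F test for one SNP."""
    n = len(y)
    cols = [np.ones(n)]
    if covariates is not None:
        cols.append(covariates)
    cols.append(x)
    A = np.column_stack(cols)
    q = A.shape[1]
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    s2 = (r @ r) / (n - q)
    se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[-1, -1])
    F = (beta[-1] / se) ** 2
    return beta[-1], se, stats.f.sf(F, 1, n - q)


class TestLdPrune:
    def test_correlated_pair_loses_later_snp(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 100).astype(float)
        noise = rng.integers(0, 3, 100).astype(float)
        y = np.where(rng.random(100) < 0.8, x, noise)  # r2 ~ 0.5
        gm = make_gm(np.column_stack([x, y]))
        kept = ld_prune(gm)
        assert list(kept) == [0]

    def test_uncorrelated_pair_survives(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.integers(0, 3, (200, 2)).astype(float))
        assert list(ld_prune(gm)) == [0, 1]

    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 50).astype(float)
        gm = make_gm(np.column_stack([x, x, x]))
        assert list(ld_prune(gm)) == [0]

    def test_no_retained_pair_exceeds_threshold_within_block(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, (120, 10)).astype(float)
        cols = [base[:, i // 3] if i % 3 == 0 else
                rng.integers(0, 3, 120).astype(float) for i in range(30)]
        gm = make_gm(np.column_stack(cols))
        kept = ld_prune(gm, window_snps=30, step_snps=30, r2_threshold=0.2)
        sub = gm.dosage[:, kept]
        r2 = np.corrcoef(sub.T) ** 2
        iu = np.triu_indices(len(kept), 1)
        assert (r2[iu] < 0.2).all()


class TestBonferroni:
    def test_published_snp_count(self):
        cutoff = bonferroni_threshold(165_202)
        assert cutoff == pytest.approx(6.05e-6, rel=1e-3)

    @pytest.mark.parametrize("m, expected", [(1, 1.0), (100, 0.01)])
    def test_simple_values(self, m, expected):
        assert bonferroni_threshold(m) == expected

    def test_zero_tests_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestKinship:
    def test_duplicated_sample_matches_diagonal(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 300)
        d = ((rng.random((20, 300)) < p).astype(float)
             + (rng.random((20, 300)) < p))
        d[1] = d[0]
        K, samples = kinship(make_gm(d))
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_diagonal_near_one_and_psd_for_hwe_data(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 2000)
        d = ((rng.random((60, 2000)) < p).astype(float)
             + (rng.random((60, 2000)) < p))
        K, _ = kinship(make_gm(d))
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.05)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


@pytest.fixture(scope="module")
def gwas_cohort():
    cohort = sim.simulate_cohort(n_snps=3000, n_chrom=3,
                                 chrom_length_bp=10_000_000,
                                 missing_rate=0.02, seed=31)
    gm, _ = filter_snps(cohort.gm, min_maf=0.05)
    return cohort, gm


class TestMlmScan:
    def test_identity_kinship_equals_ols_oracle(self, gwas_cohort):
        cohort, gm = gwas_cohort
        gm = gm.take_snps(np.arange(40))
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=gm.n_samples), index=gm.samples)
        res = mlm_scan(gm, y, kinship_matrix=np.eye(gm.n_samples),
                       covariates=None, min_maf=0.05)
        dose = gm.dosage.astype(float)
        mu = np.nanmean(dose, axis=0)
        dose = np.where(np.isnan(dose), mu, dose)
        ids = {v: j for j, v in enumerate(gm.variants["id"])}
        for _, row in res.table.iterrows():
            eff, se, p = ols_oracle(y.to_numpy(), dose[:, ids[row["id"]]])
            assert row["effect"] == pytest.approx(eff, rel=1e-6)
            assert row["se"] == pytest.approx(se, rel=1e-6)
            assert row["p"] == pytest.approx(p, rel=1e-6)

    def test_null_phenotype_type_one_error_calibrated(self, gwas_cohort):
        cohort, gm = gwas_cohort
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=gm.n_samples), index=gm.samples)
        res = mlm_scan(gm, y, covariates=3)
        frac = float((res.table["p"] <= 0.05).mean())
        assert 0.02 <= frac <= 0.09

    def test_planted_causal_snp_is_rank_one(self, gwas_cohort):
        cohort, gm = gwas_cohort
        # pick a common SNP so it survives the MAF filter
        from zeapop.genotypes import maf
        common = int(np.nanargmax(maf(cohort.gm)))
        trait = sim.TraitModel((common,), (2.0,), h2_polygenic=0.3,
                               noise_sd=1.0)
        ph = sim.simulate_phenotype(cohort, trait, seed=10)
        y = ph.set_index("sample")["value"]
        res = mlm_scan(gm, y, covariates=3)
        lead = res.table.loc[res.table["p"].idxmin()]
        assert lead["id"] == cohort.gm.variants.iloc[common]["id"]

    def test_missing_phenotypes_dropped(self, gwas_cohort):
        cohort, gm = gwas_cohort
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=gm.n_samples), index=gm.samples)
        y.iloc[:10] = np.nan
        res = mlm_scan(gm.take_snps(np.arange(50)), y, covariates=None)
        assert res.n_samples == gm.n_samples - 10

    def test_singular_covariates_error(self, gwas_cohort):
        cohort, gm = gwas_cohort
        y = pd.Series(np.zeros(gm.n_samples) + 1.0, index=gm.samples)
        bad = np.ones((gm.n_samples, 1))  # collinear with the intercept
        with pytest.raises(ValueError):
            mlm_scan(gm.take_snps(np.arange(10)), y, covariates=bad)


class TestResolveLoci:
    def _result(self, rows):
        tab = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt",
                                          "maf", "effect", "se", "stat", "p"])
        return AssociationResult(tab)

    def test_nearby_significant_snps_form_one_locus(self):
        res = self._result([("chr1", 1_000_000, "a", "A", "T", 0.2, 1, 0.1,
                             10, 1e-8),
                            ("chr1", 1_500_000, "b", "A", "T", 0.3, 1, 0.1,
                             9, 1e-7)])
        loci = resolve_loci(res, cutoff=1e-6)
        assert len(loci) == 1
        assert loci["lead_id"].iloc[0] == "a"
        assert loci["n_snps"].iloc[0] == 2

    def test_different_chromosomes_are_distinct_loci(self):
        res = self._result([("chr1", 1, "a", "A", "T", 0.2, 1, 0.1, 10, 1e-8),
                            ("chr2", 1, "b", "A", "T", 0.2, 1, 0.1, 10, 1e-8)])
        assert len(resolve_loci(res, cutoff=1e-6)) == 2

    def test_loci_never_outnumber_significant_snps(self):
        rng = np.random.default_rng(12)
        rows = [("chr1", int(p), f"s{i}", "A", "T", 0.2, 1, 0.1, 10,
                 10 ** -rng.uniform(2, 9))
                for i, p in enumerate(np.sort(rng.integers(1, 10**8, 50)))]
        res = self._result(rows)
        cutoff = 1e-4
        loci = resolve_loci(res, cutoff)
        n_sig = (res.table["p"] <= cutoff).sum()
        assert 0 < len(loci) <= n_sig
        assert loci["n_snps"].sum() == n_sig

    def test_no_significant_snps_empty_result(self):
        res = self._result([("chr1", 1, "a", "A", "T", 0.2, 1, 0.1, 1, 0.5)])
        assert resolve_loci(res, cutoff=1e-6).empty


class TestGroupFreqContrast:
    def test_inbred_frequency_shift(self):
        rng = np.random.default_rng(13)
        n = 100
        trop = 2.0 * (rng.random(n) < 0.7)   # C allele freq 0.7
        temp = 2.0 * (rng.random(n) < 0.95)  # C allele freq 0.95
        gm = make_gm(np.concatenate([trop, temp]).reshape(-1, 1))
        groups = pd.Series(["tropical"] * n + ["temperate"] * n,
                           index=gm.samples)
        out = group_freq_contrast(gm, groups, 0, "T")
        # exact agreement with the realized fraction of homozygous lines
        assert out["tropical"] == pytest.approx(np.mean(trop == 2.0))
        assert out["temperate"] == pytest.approx(np.mean(temp == 2.0))
        # and the realized fractions sit near the planted shift
        assert out["tropical"] == pytest.approx(0.7, abs=0.15)
        assert out["temperate"] == pytest.approx(0.95, abs=0.1)
        assert out["temperate"] > out["tropical"]

    def test_fixed_allele_is_100_percent(self):
        gm = make_gm(np.full((5, 1), 2.0))
        groups = pd.Series(["g"] * 5, index=gm.samples)
        assert group_freq_contrast(gm, groups, 0, "T")["g"] == 1.0
        assert group_freq_contrast(gm, groups, 0, "A")["g"] == 0.0

    def test_unknown_allele_errors(self):
        gm = make_gm(np.zeros((3, 1)))
        groups = pd.Series(["g"] * 3, index=gm.samples)
        with pytest.raises(ValueError):
            group_freq_contrast(gm, groups, 0, "G")

    def test_group_with_no_calls_is_nan(self):
        d = np.array([[0.0], [np.nan]])
        gm = make_gm(d)
        groups = pd.Series(["a", "b"], index=gm.samples)
        out = group_freq_contrast(gm, groups, 0, "T")
        assert np.isnan(out["b"])
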
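"""F_ST estimator against an independent Weir–Cockerham transcription, and
the composite-likelihood sweep statistic."""

import numpy as np
import pandas as pd
import pytest

from zeapop.scan import (DEFAULT_S_GRID, estimate_omega, global_fst,
                         pairwise_global_fst, wc_fst_components, wc_fst_snp,
                         windowed_fst, xpclr_scan, xpclr_window)
from zeapop.genotypes import allele_freq

from conftest import make_gm


def wc_oracle(genos1, genos2):
    """Independent scalar transcription of Weir & Cockerham (1984), eq. 2-4.

    Takes two lists of diploid genotypes (0/1/2 alt-allele counts, None for
    missing) for ONE SNP and returns (a, b, c) computed step by step.
    """
    g1 = [g for g in genos1 if g is not None]
    g2 = [g for g in genos2 if g is not None]
    r = 2
    n1, n2 = len(g1), len(g2)
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - 1.0 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_matches_oracle_on_hand_example(self):
        # pop1: 10 diploids, 12/20 alt alleles; pop2: 10 diploids, 4/20
        g1 = [2, 2, 2, 1, 1, 1, 1, 1, 1, 0]
        g2 = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        comps, theta = wc_fst_snp(g1, g2)
        a, b, c = wc_oracle(g1, g2)
        assert comps.a[0] == pytest.approx(a, abs=1e-10)
        assert comps.b[0] == pytest.approx(b, abs=1e-10)
        assert comps.c[0] == pytest.approx(c, abs=1e-10)
        assert theta == pytest.approx(a / (a + b + c), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_with_missing_data(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.integers(0, 3, 15).astype(float)
        g2 = rng.integers(0, 3, 12).astype(float)
        g1[rng.integers(0, 15, 3)] = np.nan
        comps, _ = wc_fst_snp(g1, g2)
        a, b, c = wc_oracle([None if np.isnan(g) else int(g) for g in g1],
                            [int(g) for g in g2])
        assert comps.a[0] == pytest.approx(a, abs=1e-10)
        assert comps.b[0] == pytest.approx(b, abs=1e-10)
        assert comps.c[0] == pytest.approx(c, abs=1e-10)

    def test_fixed_difference_approaches_one(self):
        _, theta = wc_fst_snp([2] * 200, [0] * 200)
        assert theta == pytest.approx(1.0, abs=0.01)

    def test_no_differentiation_near_zero(self):
        g = [0] * 25 + [1] * 50 + [2] * 25  # HWE p = 0.5
        _, theta = wc_fst_snp(g, g)
        assert theta <= 0.05

    def test_missing_population_gives_nan_components(self):
        comps = wc_fst_components(np.full((3, 1), np.nan),
                                  np.array([[0.0], [1.0], [2.0]]))
        assert np.isnan(comps.a[0])


class TestWindowedFst:
    def test_weighted_ratio_differs_from_mean_of_ratios(self):
        import zeapop.scan as scan
        comps = scan.FstComponents(a=np.array([0.1, 0.0]),
                                   b=np.array([0.1, 0.8]),
                                   c=np.array([0.0, 0.0]))
        variants = pd.DataFrame({"chrom": "chr1", "pos": [10_000, 20_000],
                                 "id": ["a", "b"], "ref": "A", "alt": "T"})
        track = windowed_fst(variants, comps, {"chr1": 100_000},
                             window_bp=100_000, step_bp=100_000, min_snps=2)
        assert track["score"].iloc[0] == pytest.approx(0.1)
        mean_of_ratios = np.mean(comps.theta)
        assert mean_of_ratios == pytest.approx(0.25)

    def test_windows_below_min_snps_dropped(self):
        import zeapop.scan as scan
        comps = scan.FstComponents(*(np.array([0.1]),) * 3)
        variants = pd.DataFrame({"chrom": "chr1", "pos": [10_000],
                                 "id": ["a"], "ref": "A", "alt": "T"})
        track = windowed_fst(variants, comps, {"chr1": 100_000},
                             window_bp=100_000, step_bp=100_000, min_snps=5)
        assert track.empty

    def test_window_sum_matches_oracle_component_sums(self):
        rng = np.random.default_rng(5)
        n1, n2, m = 20, 15, 12
        d1 = rng.integers(0, 3, (n1, m)).astype(float)
        d2 = rng.integers(0, 3, (n2, m)).astype(float)
        comps = wc_fst_components(d1, d2)
        variants = pd.DataFrame({"chrom": "chr1",
                                 "pos": 1000 * np.arange(1, m + 1),
                                 "id": "x", "ref": "A", "alt": "T"})
        track = windowed_fst(variants, comps, {"chr1": 100_000},
                             window_bp=100_000, step_bp=100_000, min_snps=5)
        num = den = 0.0
        for j in range(m):
            a, b, c = wc_oracle(d1[:, j].astype(int), d2[:, j].astype(int))
            num += a
            den += a + b + c
        assert track["score"].iloc[0] == pytest.approx(num / den, abs=1e-10)

    def test_zero_component_window_scores_zero(self):
        import zeapop.scan as scan
        comps = scan.FstComponents(a=np.zeros(6), b=np.full(6, 0.2),
                                   c=np.zeros(6))
        variants = pd.DataFrame({"chrom": "chr1",
                                 "pos": 1000 * np.arange(1, 7),
                                 "id": "x", "ref": "A", "alt": "T"})
        track = windowed_fst(variants, comps, {"chr1": 100_000},
                             window_bp=100_000, step_bp=100_000)
        assert track["score"].iloc[0] == 0.0


class TestPairwiseGlobalFst:
    def test_duplicated_group_near_zero(self):
        rng = np.random.default_rng(1)
        n = 200
        p = rng.uniform(0.1, 0.9, 400)
        d = ((rng.random((n, 400)) < p).astype(float)
             + (rng.random((n, 400)) < p))  # HWE diploids
        gm = make_gm(np.vstack([d, d]))
        groups = pd.Series(["a"] * n + ["b"] * n, index=gm.samples)
        out = pairwise_global_fst(gm, groups)
        assert abs(out.loc["a", "b"]) < 0.01
        assert out.loc["a", "a"] == 0.0
        assert out.equals(out.T)

    def test_single_sample_group_errors(self):
        gm = make_gm(np.zeros((3, 5)))
        groups = pd.Series(["a", "a", "b"], index=gm.samples)
        with pytest.raises(ValueError):
            pairwise_global_fst(gm, groups)


class TestOmega:
    def test_zero_when_frequencies_equal(self):
        p = np.random.default_rng(0).uniform(0.1, 0.9, 500)
        assert estimate_omega(p, p) == 0.0

    def test_recovers_balding_nichols_drift(self):
        from zeapop import simulate as sim
        rng = np.random.default_rng(2)
        p_ref = sim._truncated_beta(rng, 0.8, 0.8, 0.05, 0.95, 5000)
        p_test = sim._balding_nichols(rng, p_ref, 0.1)
        assert estimate_omega(p_ref, p_test) == pytest.approx(0.1, abs=0.02)

    def test_invariant_to_allele_label_flip(self):
        rng = np.random.default_rng(3)
        p_ref = rng.uniform(0.1, 0.9, 500)
        p_test = np.clip(p_ref + rng.normal(0, 0.05, 500), 0, 1)
        assert estimate_omega(p_ref, p_test) == pytest.approx(
            estimate_omega(1 - p_ref, 1 - p_test))

    def test_too_few_informative_snps_errors(self):
        with pytest.raises(ValueError):
            estimate_omega(np.full(50, 0.5), np.full(50, 0.5))


class TestXpclr:
    def test_null_reduction_when_all_snps_escape(self):
        # enormous distances: c ~= 1 for every s in the grid -> CLR ~ 0
        p_ref = np.array([0.3, 0.5, 0.7])
        p_test = np.array([0.35, 0.45, 0.72])
        pos = np.array([1e9, 2e9, 3e9])
        clr = xpclr_window(p_ref, p_test, pos, center=0.0, omega=0.1)
        assert clr == pytest.approx(0.0, abs=1e-8)

    def test_clr_nonnegative_and_zero_under_null_fit(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p_ref = rng.uniform(0.1, 0.9, 5)
            p_test = np.clip(p_ref + rng.normal(0, 0.1, 5), 0.01, 0.99)
            pos = np.sort(rng.uniform(0, 100_000, 5))
            clr = xpclr_window(p_ref, p_test, pos, center=50_000, omega=0.1)
            assert clr >= 0.0

    def test_swept_frequencies_score_high(self):
        # test frequencies dragged to the background allele near the center
        p_ref = np.array([0.4, 0.5, 0.6, 0.5, 0.4])
        pos = np.array([48_000, 49_000, 50_000, 51_000, 52_000.0])
        swept = np.array([0.97, 0.99, 1.0, 0.99, 0.97])
        neutral = np.array([0.45, 0.5, 0.55, 0.5, 0.45])
        clr_sweep = xpclr_window(p_ref, swept, pos, 50_000, omega=0.05)
        clr_null = xpclr_window(p_ref, neutral, pos, 50_000, omega=0.05)
        assert clr_sweep > clr_null + 10

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            xpclr_window([0.0, 0.5], [0.1, 0.5], [1, 2], 1, omega=0.1)
        with pytest.raises(ValueError):
            xpclr_window([0.5], [0.5], [1], 1, omega=-0.5)

    def test_scan_uses_exactly_five_snps_and_is_seeded(self, small_cohort):
        labels = small_cohort.groups.reindex(small_cohort.gm.samples)
        merged = pd.Series(
            np.where(labels.isin(["parviglumis", "mexicana"]), "ref", "test"),
            index=small_cohort.gm.samples)
        p_ref = allele_freq(small_cohort.gm, merged, "ref")
        p_test = allele_freq(small_cohort.gm, merged, "test")
        kw = dict(window_bp=200_000, step_bp=100_000)
        a = xpclr_scan(small_cohort.gm.variants, p_ref, p_test,
                       small_cohort.chrom_sizes, seed=1, **kw)
        b = xpclr_scan(small_cohort.gm.variants, p_ref, p_test,
                       small_cohort.chrom_sizes, seed=1, **kw)
        assert (a["n_snps"] == 5).all()
        assert a.equals(b)
        assert (a["score"] >= 0).all()

    def test_ld_weights_downweight_duplicate_snps(self):
        from zeapop.scan import _ld_weights
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, (50, 1)).astype(float)
        ref = np.hstack([x, x, rng.integers(0, 3, (50, 3)).astype(float)])
        w = _ld_weights(ref, ld_r2_cap=0.95)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == pytest.approx(0.5)
        assert w[2:] == pytest.approx([1.0, 1.0, 1.0])
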
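"""Simulator: genotype distributional checks, LD pruning, phenotype model."""

import numpy as np
import pytest
from scipy import stats

from tissuemix.simulate import (
    SHARED,
    SimConfig,
    default_scenario_grid,
    ld_prune,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_shared_effects,
)


class TestGenotypes:
    def test_binomial_moments_at_half(self):
        X, _ = simulate_genotypes(20_000, 5, maf_range=(0.5, 0.5), seed=0)
        np.testing.assert_allclose(X.mean(axis=0), 1.0, atol=0.03)
        np.testing.assert_allclose(X.var(axis=0), 0.5, atol=0.03)

    def test_point_maf_range(self):
        X, mafs = simulate_genotypes(50_000, 10, maf_range=(0.01, 0.01), seed=1)
        np.testing.assert_allclose(mafs, 0.01)
        np.testing.assert_allclose(X.mean(axis=0) / 2, 0.01, atol=0.005)

    def test_hwe_holds_across_columns(self):
        """Genotype frequencies should pass a HWE chi-square test for >99%
        of columns at alpha = 0.001."""
        n, m = 4000, 1000
        X, mafs = simulate_genotypes(n, m, seed=7)
        fails = 0
        for j in range(m):
            counts = np.bincount(X[:, j].astype(int), minlength=3)
            p = counts @ np.array([0, 1, 2]) / (2 * n)
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            keep = expected > 0
            chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            if stats.chi2.sf(chi2, df=1) < 0.001:
                fails += 1
        assert fails / m < 0.01

    def test_monomorphic_columns_redrawn(self):
        X, _ = simulate_genotypes(30, 50, maf_range=(0.01, 0.02), seed=2)
        assert np.all(X.std(axis=0) > 0)

    def test_ar_mode_induces_adjacent_correlation(self):
        X, _ = simulate_genotypes(5000, 30, maf_range=(0.2, 0.4), seed=3,
                                  rho=0.8)
        r = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(29)]
        assert np.mean(r) > 0.3

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, maf_range=(0.0, 0.5), seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, maf_range=(0.3, 0.6), seed=0)


class TestLdPrune:
    def naive_prune(self, X, r2_max):
        keep = [0]
        for j in range(1, X.shape[1]):
            r2 = np.corrcoef(X[:, keep[-1]], X[:, j])[0, 1] ** 2
            if r2 < r2_max:
                keep.append(j)
        return keep

    def test_duplicate_column_dropped(self, rng):
        x = rng.binomial(2, 0.3, size=200).astype(float)
        X = np.column_stack([x, x, rng.binomial(2, 0.3, size=200)])
        kept = ld_prune(X)
        assert 1 not in kept and 0 in kept

    def test_independent_snps_mostly_retained(self):
        X, _ = simulate_genotypes(2000, 100, seed=4)
        kept = ld_prune(X.astype(float))
        assert len(kept) >= 98

    def test_consecutive_pair_semantics(self, rng):
        # middle SNP in LD with first (r2 >= 0.25): dropped; third compared
        # against the FIRST (last retained), not the dropped middle
        x1 = rng.standard_normal(500)
        x2 = 0.7 * x1 + 0.4 * rng.standard_normal(500)   # r2 ~ 0.75 with x1
        x3 = rng.standard_normal(500)                     # independent
        kept = ld_prune(np.column_stack([x1, x2, x3]))
        assert list(kept) == [0, 2]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((300, 6))
        # correlate some adjacent columns
        for j in range(1, 6):
            if rng.random() < 0.5:
                base[:, j] = 0.8 * base[:, j - 1] + 0.3 * base[:, j]
        assert list(ld_prune(base)) == self.naive_prune(base, 0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ld_prune(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestPhenotypes:
    def test_null_heritability_is_pure_noise(self):
        cfg = SimConfig(n=4000, m=(30, 30), h2=(0.0, 0.0), seed=9)
        Y, truth, blocks = simulate_dataset(cfg)
        rows = truth.C == 0
        assert Y[rows].var() == pytest.approx(10.0, rel=0.1)
        corrs = [abs(np.corrcoef(Y[rows], blocks[0].genotypes[rows, j])[0, 1])
                 for j in range(10)]
        assert np.mean(corrs) < 0.05

    def test_variance_decomposition_at_high_h2(self):
        cfg = SimConfig(n=8000, m=(50, 50), h2=(0.9, 0.9), seed=10)
        Y, truth, blocks = simulate_dataset(cfg)
        for k in range(2):
            rows = truth.C == k
            genetic = blocks[k].genotypes[rows] @ truth.beta[k]
            ratio = genetic.var() / Y[rows].var()
            assert ratio == pytest.approx(0.9, abs=0.05)

    def test_quota_assignment_counts(self):
        cfg = SimConfig(n=999, m=(5, 5), w=(1 / 3, 2 / 3), h2=(0.2, 0.2),
                        seed=1)
        _, truth, _ = simulate_dataset(cfg)
        assert (truth.C == 0).sum() == 333
        assert (truth.C == 1).sum() == 666

    def test_byte_reproducible_under_seed(self):
        cfg = SimConfig(n=500, m=(10, 10), h2=(0.3, 0.3), seed=33)
        Y1, t1, b1 = simulate_dataset(cfg)
        Y2, t2, b2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(Y1, Y2)
        np.testing.assert_array_equal(t1.C, t2.C)
        np.testing.assert_array_equal(b1[0].genotypes, b2[0].genotypes)

    def test_blocks_standardized_on_full_sample(self):
        cfg = SimConfig(n=2000, m=(20, 20), h2=(0.4, 0.4), seed=2)
        _, _, blocks = simulate_dataset(cfg)
        for b in blocks:
            np.testing.assert_allclose(b.genotypes.mean(0), 0, atol=1e-10)
            np.testing.assert_allclose(b.genotypes.var(0), 1, atol=1e-10)

    def test_baseline_means_shift_components(self):
        cfg = SimConfig(n=6000, m=(10, 10), h2=(0.0, 0.0), alpha=(0.0, 3.0),
                        seed=4)
        Y, truth, _ = simulate_dataset(cfg)
        assert Y[truth.C == 1].mean() - Y[truth.C == 0].mean() == \
            pytest.approx(3.0, abs=0.3)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n=100, m=(5, 5), h2=(1.2, 0.1))

    def test_mismatched_dosages_rejected(self, rng):
        cfg = SimConfig(n=100, m=(5, 5), h2=(0.1, 0.1), seed=0)
        X = rng.binomial(2, 0.3, size=(100, 4)).astype(np.int8)
        with pytest.raises(ValueError):
            simulate_phenotypes(cfg, [X, X])


class TestSharedEffects:
    def test_three_group_structure(self):
        Y, truth, blocks = simulate_shared_effects(500, m=(30, 30), h2=0.3,
                                                   seed=6)
        assert len(Y) == 1500
        assert (truth.groups == "both").sum() == 500
        assert set(truth.C[truth.groups == "both"]) == {SHARED}
        # total variance stays near sigma2_y in every group
        for g in ("tissue_1", "both", "tissue_2"):
            assert Y[truth.groups == g].var() == pytest.approx(10.0, rel=0.25)

    def test_shared_group_draws_from_both_snp_sets(self):
        Y, truth, blocks = simulate_shared_effects(2000, m=(40, 40), h2=0.6,
                                                   seed=8)
        rows = truth.groups == "both"
        for k in range(2):
            genetic = blocks[k].genotypes[rows] @ truth.beta[k]
            r = np.corrcoef(Y[rows], genetic)[0, 1]
            assert r > 0.3  # each tissue contributes about half the signal


def test_default_grid_matches_study_design():
    grid = default_scenario_grid()
    ns = {c.n for c in grid}
    ms = {c.m for c in grid}
    assert ns == {40_000, 100_000}
    assert ms == {(1000, 1000), (1000, 1500), (1500, 1000), (1500, 1500)}
    h2s = {c.h2 for c in grid}
    assert (0.0, 0.0) in h2s and (0.9, 0.9) in h2s and (0.1, 0.5) in h2s
    assert all(c.sigma2_y == (10.0, 10.0) for c in grid)
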
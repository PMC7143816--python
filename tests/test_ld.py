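import numpy as np
import pytest

from divscan import (
    SimulationConfig,
    block_haplotypes,
    dprime_ci,
    dprime_r2,
    gabriel_blocks,
    pairwise_ld,
    simulate_dataset,
    two_locus_em,
)
from divscan.ld import HaplotypeBlock, genotype_pair_counts

from _oracles import em_grid_loglik
from conftest import make_dataset


def counts_from_haplotype_pairs(pairs):
    """3x3 genotype table from a list of ((a1,b1),(a2,b2)) haplotype pairs."""
    t = np.zeros((3, 3), dtype=int)
    for (a1, b1), (a2, b2) in pairs:
        t[a1 + a2, b1 + b2] += 1
    return t


class TestTwoLocusEm:
    def test_no_double_heterozygotes_closed_form(self):
        # 4 individuals, phase unambiguous
        pairs = [((1, 1), (1, 1)), ((1, 1), (0, 0)), ((0, 0), (0, 0)), ((1, 0), (1, 0))]
        t = counts_from_haplotype_pairs(pairs)
        f = two_locus_em(t)
        np.testing.assert_allclose(f, [3 / 8, 2 / 8, 0, 3 / 8], atol=1e-9)

    def test_perfect_coupling(self):
        t = counts_from_haplotype_pairs([((1, 1), (1, 1))] * 5 + [((0, 0), (0, 0))] * 5)
        f = two_locus_em(t)
        np.testing.assert_allclose(f, [0.5, 0, 0, 0.5], atol=1e-9)
        dp, r2 = dprime_r2(f)
        assert dp == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_em_beats_grid_search(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(0, 6, size=(3, 3))
            if t.sum() == 0:
                continue
            two_n = 2 * t.sum()
            pA = (2 * t[2, :].sum() + t[1, :].sum()) / two_n
            pB = (2 * t[:, 2].sum() + t[:, 1].sum()) / two_n
            if min(pA, 1 - pA, pB, 1 - pB) == 0:
                continue
            f = two_locus_em(t)
            ll_em = em_grid_loglik(t, f[0])
            lo = max(0.0, pA + pB - 1.0)
            hi = min(pA, pB)
            grid = np.arange(lo, hi + 1e-9, 0.01)
            ll_grid = max(em_grid_loglik(t, x) for x in grid)
            assert ll_em >= ll_grid - 1e-6

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            two_locus_em(np.zeros((3, 3)))


class TestDprimeR2:
    def test_independence(self):
        dp, r2 = dprime_r2([0.25, 0.25, 0.25, 0.25])
        assert dp == pytest.approx(0.0) and r2 == pytest.approx(0.0)

    def test_hand_example(self):
        dp, r2 = dprime_r2([0.4, 0.1, 0.1, 0.4])
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            f = rng.dirichlet(np.ones(4))
            pA, pB = f[0] + f[1], f[0] + f[2]
            if min(pA, 1 - pA, pB, 1 - pB) < 0.01:
                continue
            swapped = [f[3], f[2], f[1], f[0]]  # swap labels at both loci
            np.testing.assert_allclose(
                dprime_r2(f), dprime_r2(swapped), atol=1e-12
            )

    def test_monomorphic_flagged(self):
        with pytest.raises(ValueError):
            dprime_r2([0.5, 0.5, 0.0, 0.0])

    def test_r2_equals_genotype_correlation_without_double_hets(self):
        pairs = [((1, 1), (0, 0)), ((1, 1), (1, 1)), ((0, 0), (0, 0)),
                 ((1, 0), (1, 0)), ((0, 1), (0, 1)), ((1, 1), (1, 0))]
        t = counts_from_haplotype_pairs(pairs)
        f = two_locus_em(t)
        _, r2 = dprime_r2(f)
        g1 = [a1 + a2 for (a1, _), (a2, _) in pairs]
        g2 = [b1 + b2 for (_, b1), (_, b2) in pairs]
        assert r2 == pytest.approx(np.corrcoef(g1, g2)[0, 1] ** 2, abs=1e-9)


class TestDprimeCi:
    def test_large_sample_perfect_ld_tight(self):
        t = counts_from_haplotype_pairs(
            [((1, 1), (1, 1))] * 100 + [((0, 0), (0, 0))] * 100
        )
        low, high = dprime_ci(t)
        assert low >= 0.98

    def test_two_individuals_wide(self):
        t = counts_from_haplotype_pairs([((1, 1), (0, 0)), ((0, 0), (1, 1))])
        low, high = dprime_ci(t)
        assert low < 0.5

    def test_bounds_ordered(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.integers(0, 8, size=(3, 3))
            two_n = 2 * t.sum()
            if two_n == 0:
                continue
            pA = (2 * t[2, :].sum() + t[1, :].sum()) / two_n
            pB = (2 * t[:, 2].sum() + t[:, 1].sum()) / two_n
            if min(pA, 1 - pA, pB, 1 - pB) == 0:
                continue
            low, high = dprime_ci(t)
            assert 0.0 <= low <= high <= 1.0


def perfect_ld_dataset(n_snps=3, n_ind=60, seed=0):
    """Individuals drawn from two complementary haplotypes: full LD."""
    rng = np.random.default_rng(seed)
    h = rng.integers(0, 2, size=(2 * n_ind,)) > 0
    d = np.empty((n_ind, n_snps), dtype=np.int8)
    for i in range(n_ind):
        a = h[2 * i]
        b = h[2 * i + 1]
        d[i] = int(a) + int(b)
    return make_dataset(d)


class TestGabrielBlocks:
    def test_three_snps_full_ld_one_block(self):
        ds = perfect_ld_dataset(3)
        pairs = pairwise_ld(ds, max_distance_bp=10**9)
        blocks = gabriel_blocks(pairs, ds)
        assert len(blocks) == 1
        assert (blocks[0].first_snp_index, blocks[0].last_snp_index) == (0, 2)

    def test_no_strong_ld_no_blocks(self):
        rng = np.random.default_rng(12)
        ds = make_dataset(rng.integers(0, 3, size=(60, 5)))
        pairs = pairwise_ld(ds, max_distance_bp=10**9)
        blocks = gabriel_blocks(pairs, ds)
        assert blocks == []

    def test_recombination_splits_blocks_vs_bruteforce(self):
        # two perfect-LD triples separated by an independent SNP
        rng = np.random.default_rng(3)
        n = 80
        h1 = rng.integers(0, 2, size=2 * n)
        h2 = rng.integers(0, 2, size=2 * n)
        mid = rng.integers(0, 2, size=2 * n)
        d = np.empty((n, 7), dtype=np.int8)
        for i in range(n):
            a, b = h1[2 * i], h1[2 * i + 1]
            c, e = h2[2 * i], h2[2 * i + 1]
            m1, m2 = mid[2 * i], mid[2 * i + 1]
            d[i] = [a + b] * 3 + [m1 + m2] + [c + e] * 3
        ds = make_dataset(d)
        pairs = pairwise_ld(ds, max_distance_bp=10**9)
        blocks = gabriel_blocks(pairs, ds)
        spans = {(b.first_snp_index, b.last_snp_index) for b in blocks}
        assert spans == {(0, 2), (4, 6)}

    def test_blocks_cover_most_snps_with_two_founders(self):
        # tight linkage: two haplotypes segregating with few recombinants
        cfg = SimulationConfig(
            seed=2, n_snps=48, n_chromosomes=1, n_pop1=80, n_pop2=10,
            founder_haplotypes=2, missing_rate=0.0, roh_per_individual=0,
            n_outlier_loci=1, mean_segment_snps=1000,
        )
        ds, _ = simulate_dataset(cfg)
        pop = ds.restrict_to_population("SOK")
        pairs = pairwise_ld(pop, max_distance_bp=10**9)
        blocks = gabriel_blocks(pairs, pop)
        covered = sum(b.last_snp_index - b.first_snp_index + 1 for b in blocks)
        assert covered / pop.n_snps >= 0.8


class TestBlockHaplotypes:
    def test_fully_homozygous_direct_counts(self):
        d = np.array([[2, 2, 2]] * 6 + [[0, 0, 0]] * 4, dtype=np.int8)
        ds = make_dataset(d)
        block = HaplotypeBlock("1", 0, 2, [])
        haps = block_haplotypes(ds, block)
        assert haps[0] == ("AAA", pytest.approx(0.6))
        assert haps[1] == ("BBB", pytest.approx(0.4))

    def test_two_founder_population_two_haplotypes(self, ):
        cfg = SimulationConfig(
            seed=5, n_snps=8, n_chromosomes=1, n_pop1=80, n_pop2=10,
            founder_haplotypes=2, missing_rate=0.0, roh_per_individual=0,
            n_outlier_loci=1, mean_segment_snps=500,
        )
        ds, _ = simulate_dataset(cfg)
        pop = ds.restrict_to_population("SOK")
        block = HaplotypeBlock("1", 0, 7, [])
        haps = block_haplotypes(pop, block)
        assert len(haps) >= 2
        assert haps[0][1] + haps[1][1] > 0.9
        assert abs(haps[0][1] - 0.5) < 0.15

    def test_frequencies_truncated_and_bounded(self):
        rng = np.random.default_rng(10)
        ds = make_dataset(rng.integers(0, 3, size=(40, 5)))
        haps = block_haplotypes(ds, HaplotypeBlock("1", 0, 4, []))
        total = sum(f for _, f in haps)
        assert total <= 1.0 + 1e-9
        assert all(f >= 0.01 for _, f in haps)

    def test_partition_ligate_on_long_block(self):
        cfg = SimulationConfig(
            seed=6, n_snps=16, n_chromosomes=1, n_pop1=60, n_pop2=10,
            founder_haplotypes=2, missing_rate=0.0, roh_per_individual=0,
            n_outlier_loci=1, mean_segment_snps=500,
        )
        ds, _ = simulate_dataset(cfg)
        pop = ds.restrict_to_population("SOK")
        haps = block_haplotypes(
            pop, HaplotypeBlock("1", 0, 15, []), enumeration_bound=8
        )
        assert len(haps) >= 2
        assert haps[0][1] + haps[1][1] > 0.8
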
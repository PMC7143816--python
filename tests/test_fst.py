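import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divscan import (
    LocusFst,
    SnpRecord,
    WindowFst,
    build_regions,
    empirical_threshold,
    per_locus_fst,
    sliding_window_scan,
    summary_fst,
    wc_components,
)

from _oracles import wc_components_exact, window_means_bruteforce
from conftest import make_dataset


class TestWcComponents:
    def test_fixed_opposite_loci_approach_one(self):
        a, b, c = wc_components(100, 1.0, 0.0, 100, 0.0, 0.0)
        fst = a / (a + b + c)
        assert fst > 0.995

    def test_no_between_population_variance(self):
        a, b, c = wc_components(50, 0.3, 0.42, 50, 0.3, 0.42)
        assert a < 0
        assert a / (a + b + c) <= 0

    def test_monomorphic_gives_nan(self):
        a, b, c = wc_components(50, 0.0, 0.0, 40, 0.0, 0.0)
        assert (a, b, c) == (0.0, 0.0, 0.0)
        assert math.isnan(LocusFst("x", a, b, c).fst)

    def test_fewer_than_two_diploids_flagged(self):
        assert all(math.isnan(v) for v in wc_components(1, 0.5, 1.0, 50, 0.3, 0.4))

    @given(
        st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)),
        st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_rational_oracle(self, c1, c2):
        n1, n2 = sum(c1), sum(c2)
        if n1 < 2 or n2 < 2:
            return
        p1 = (2 * c1[2] + c1[1]) / (2 * n1)
        h1 = c1[1] / n1
        p2 = (2 * c2[2] + c2[1]) / (2 * n2)
        h2 = c2[1] / n2
        got = wc_components(n1, p1, h1, n2, p2, h2)
        want = wc_components_exact(n1, c1, n2, c2)
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


class TestPerLocusFst:
    def test_identical_populations_nonpositive(self):
        block = np.array([[0, 1, 2, 1], [2, 1, 0, 1], [1, 1, 1, 0]])
        ds = make_dataset(
            np.vstack([block, block]), populations=["A"] * 3 + ["B"] * 3
        )
        for locus in per_locus_fst(ds):
            assert math.isnan(locus.fst) or locus.fst <= 1e-12

    def test_outlier_loci_stand_out(self, planted_outlier_scan):
        _, ds, truth = planted_outlier_scan
        fst = np.array([l.fst for l in per_locus_fst(ds)])
        out = np.zeros(len(fst), dtype=bool)
        out[truth.outlier_indices] = True
        assert np.nanmean(fst[out]) > np.nanmean(fst[~out]) + 0.1

    def test_population_selection_errors(self):
        ds = make_dataset([[0], [1], [2]], populations=["A", "B", "C"])
        with pytest.raises(ValueError):
            per_locus_fst(ds)
        with pytest.raises(ValueError):
            per_locus_fst(ds, ("A", "A"))


class TestSummaryFst:
    def test_single_locus(self):
        m, w = summary_fst([LocusFst("x", 1.0, 0.5, 0.5)])
        assert m == w == pytest.approx(0.5)

    def test_mean_vs_weighted_hand_examples(self):
        loci = [LocusFst("a", 1, 0, 1), LocusFst("b", 0, 0, 2)]
        assert summary_fst(loci) == (pytest.approx(0.25), pytest.approx(0.25))
        loci = [LocusFst("a", 1, 0, 1), LocusFst("b", 0, 0, 6)]
        assert summary_fst(loci) == (pytest.approx(0.25), pytest.approx(0.125))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        loci = [
            LocusFst(str(i), rng.normal(), abs(rng.normal()), abs(rng.normal()))
            for i in range(50)
        ]
        perm = [loci[i] for i in rng.permutation(50)]
        np.testing.assert_allclose(summary_fst(loci), summary_fst(perm), rtol=1e-12)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            summary_fst([LocusFst("x", 0.0, 0.0, 0.0)])


def snps_on(chrom_sizes, spacing=1000):
    out = []
    for c, size in chrom_sizes.items():
        out += [
            SnpRecord(f"{c}_{i}", c, (i + 1) * spacing, "A", "B") for i in range(size)
        ]
    return out


class TestSlidingWindows:
    def test_constant_track(self):
        snps = snps_on({"1": 15})
        loci = [LocusFst(s.snp_id, 0.05, 0.5, 0.45) for s in snps]
        wins = sliding_window_scan(loci, snps)
        assert len(wins) == 6
        assert all(w.mean_fst == pytest.approx(0.05) for w in wins)

    def test_window_count_and_chromosome_boundaries(self):
        snps = snps_on({"1": 12, "2": 9})
        loci = [LocusFst(s.snp_id, 0.1, 0.4, 0.5) for s in snps]
        wins = sliding_window_scan(loci, snps, window_size=10)
        assert len(wins) == 3  # chromosome 2 is too short
        assert {w.chromosome for w in wins} == {"1"}

    def test_matches_bruteforce_reaveraging(self):
        rng = np.random.default_rng(2)
        snps = snps_on({"1": 40, "2": 25, "3": 5})
        fst = rng.normal(0.02, 0.05, size=len(snps))
        fst[rng.choice(len(snps), 6, replace=False)] = np.nan
        loci = []
        for s, v in zip(snps, fst):
            loci.append(
                LocusFst(s.snp_id, v, 1.0 - v, 0.0)
                if np.isfinite(v)
                else LocusFst(s.snp_id, 0.0, 0.0, 0.0)
            )
        got = [w.mean_fst for w in sliding_window_scan(loci, snps)]
        want = window_means_bruteforce(
            [l.fst for l in loci], [s.chromosome for s in snps], 10
        )
        np.testing.assert_allclose(got, want, atol=1e-15)


class TestEmpiricalThreshold:
    def mk(self, means):
        return [
            WindowFst("1", (i,), 1 + i, 2 + i, m) for i, m in enumerate(means)
        ]

    def test_order_statistic(self):
        wins = self.mk([0.001 * r for r in range(1, 1001)])
        assert empirical_threshold(wins, 0.999) == pytest.approx(0.999)
        assert sum(w.mean_fst > 0.999 for w in wins) == 1

    def test_all_equal_zero_exceedances(self):
        wins = self.mk([0.02] * 50)
        thr = empirical_threshold(wins, 0.999)
        assert thr == 0.02
        assert sum(w.mean_fst > thr for w in wins) == 0

    def test_quantile_monotonicity_and_validation(self):
        wins = self.mk(np.random.default_rng(3).random(200))
        assert empirical_threshold(wins, 0.99) <= empirical_threshold(wins, 0.999)
        with pytest.raises(ValueError):
            empirical_threshold(wins, 1.0)


class TestBuildRegions:
    def test_extension_arithmetic(self):
        w = WindowFst("3", tuple(range(10)), 100_000, 150_000, 0.2)
        (reg,) = build_regions([w], extension_bp=25_000)
        assert (reg.start_bp, reg.end_bp) == (75_000, 175_000)
        assert reg.size_bp == 100_000

    def test_overlapping_windows_merge(self):
        w1 = WindowFst("1", tuple(range(0, 10)), 1_000, 10_000, 0.2)
        w2 = WindowFst("1", tuple(range(1, 11)), 2_000, 11_000, 0.3)
        regs = build_regions([w1, w2])
        assert len(regs) == 1
        assert regs[0].n_windows_merged == 2
        assert regs[0].peak_window_fst == 0.3

    def test_start_floored_at_one(self):
        w = WindowFst("1", tuple(range(10)), 5_000, 9_000, 0.2)
        (reg,) = build_regions([w], extension_bp=25_000)
        assert reg.start_bp == 1
        assert reg.size_bp == reg.end_bp - reg.start_bp

    def test_merged_regions_disjoint(self):
        rng = np.random.default_rng(5)
        wins = []
        for i in range(30):
            s = int(rng.integers(1, 500)) * 1_000
            wins.append(
                WindowFst("1", tuple(range(10 * i, 10 * i + 10)), s, s + 9_000, 0.1)
            )
        regs = build_regions(wins, extension_bp=0)
        regs = sorted(regs, key=lambda r: r.start_bp)
        for r1, r2 in zip(regs, regs[1:]):
            assert r1.end_bp < r2.start_bp
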
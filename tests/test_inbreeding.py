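import numpy as np
import pytest

from divscan import (
    MISSING,
    SimulationConfig,
    detect_roh,
    f_roh,
    grm,
    inbreeding_coefficients,
    ne_ld,
    simulate_dataset,
)
from divscan.inbreeding import waples_ne

from _oracles import grm_bruteforce
from conftest import make_dataset


class TestGrm:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 200)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        ds = make_dataset(d)
        np.testing.assert_allclose(
            grm(ds), grm_bruteforce(ds.dosages), atol=1e-10
        )

    def test_duplicated_sample_off_diagonal_matches_diagonal(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(15, 300)).astype(np.int8)
        d[1] = d[0]
        g = grm(make_dataset(d))
        assert g[0, 1] == pytest.approx(g[0, 0], abs=1e-9)

    def test_unrelated_population_near_zero_off_diagonal(self):
        # mean off-diagonal is -1/(n-1) by construction, so the +/-0.02 band
        # needs study-scale n
        cfg = SimulationConfig(
            seed=2, n_snps=5000, n_pop1=107, n_pop2=5, founder_haplotypes=2000,
            missing_rate=0.0, roh_per_individual=0, n_outlier_loci=1,
        )
        ds, _ = simulate_dataset(cfg)
        g = grm(ds.restrict_to_population("SOK"))
        off = g[~np.eye(g.shape[0], dtype=bool)]
        assert abs(off.mean()) < 0.02


class TestInbreedingCoefficients:
    def test_f_u_closed_form_at_half_frequency(self):
        # four samples engineered so every locus has p = 0.5
        d = np.array([[1] * 40, [1] * 40, [0, 2] * 20, [2, 0] * 20], dtype=np.int8)
        rep = inbreeding_coefficients(make_dataset(d))
        assert rep.f_u[0] == pytest.approx(-1.0)  # all heterozygous
        assert rep.f_u[2] == pytest.approx(1.0)  # all homozygous
        assert rep.f_u[3] == pytest.approx(1.0)

    def test_population_means_near_zero_outbred(self):
        cfg = SimulationConfig(
            seed=5, n_snps=4000, n_pop1=60, n_pop2=5, founder_haplotypes=2000,
            missing_rate=0.0, roh_per_individual=0, n_outlier_loci=1,
        )
        ds, _ = simulate_dataset(cfg)
        rep = inbreeding_coefficients(ds.restrict_to_population("SOK"))
        for arr in (rep.f_grm, rep.f_mom, rep.f_u):
            assert abs(np.nanmean(arr)) < 0.02

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(10, 80)).astype(np.int8)
        ds = make_dataset(d)
        rep1 = inbreeding_coefficients(ds)
        perm = rng.permutation(80)
        rep2 = inbreeding_coefficients(make_dataset(d[:, perm]))
        np.testing.assert_allclose(rep1.f_u, rep2.f_u, atol=1e-12)
        np.testing.assert_allclose(rep1.f_mom, rep2.f_mom, atol=1e-12)

    def test_roh_burden_raises_f_u(self):
        cfg = SimulationConfig(
            seed=7, n_snps=3000, n_pop1=30, n_pop2=30, founder_haplotypes=300,
            missing_rate=0.0, roh_per_individual=0, n_outlier_loci=1,
        )
        ds, _ = simulate_dataset(cfg)
        sok = ds.restrict_to_population("SOK")
        # plant heavy ROH burden in 5 individuals: 25% of loci homozygosed
        d = sok.dosages.copy()
        span = slice(0, 750)
        for i in range(5):
            col = d[i, span]
            col[col == 1] = 2 * (np.random.default_rng(i).random((col == 1).sum()) < 0.5)
            d[i, span] = col
        ds2 = make_dataset(
            d, populations=sok.populations,
            chrom=[s.chromosome for s in sok.snps],
            positions=[s.position_bp for s in sok.snps],
        )
        rep = inbreeding_coefficients(ds2)
        assert rep.f_u[:5].mean() > np.nanmean(rep.f_u) + 0.15 * 0.25


def homozygous_run_dataset(n_snps=120, spacing=50_000, run=slice(30, 80)):
    rng = np.random.default_rng(11)
    d = rng.integers(0, 3, size=(1, n_snps)).astype(np.int8)
    d[0, run] = 2 * rng.integers(0, 2, size=run.stop - run.start)
    # heterozygous sentinels so the maximal run is exactly the planted one
    d[0, run.start - 1] = 1
    d[0, run.stop] = 1
    return make_dataset(d, positions=[spacing * (j + 1) for j in range(n_snps)])


class TestDetectRoh:
    def test_fully_heterozygous_no_segments(self):
        d = np.ones((1, 100), dtype=np.int8)
        ds = make_dataset(d, positions=[50_000 * (j + 1) for j in range(100)])
        assert detect_roh(ds) == []

    def test_short_run_rejected_by_snp_count(self):
        # 29 homozygous SNPs spanning 1.5 Mb: fails the 30-SNP rule
        d = np.ones((1, 31), dtype=np.int8)
        d[0, 1:30] = 2
        ds = make_dataset(d, positions=[1 + j * 53_000 for j in range(31)])
        assert detect_roh(ds, min_snps=30, min_length_bp=1_000_000) == []

    def test_detects_planted_run_with_tight_boundaries(self):
        ds = homozygous_run_dataset()
        segs = detect_roh(ds, min_snps=30, min_length_bp=1_000_000, max_missing=0)
        assert len(segs) >= 1
        seg = max(segs, key=lambda s: s.length_bp)
        pos = ds.positions()
        assert seg.start_bp == pos[30]
        assert seg.end_bp == pos[79]

    def test_missing_allowance(self):
        ds = homozygous_run_dataset()
        ds.dosages[0, 50] = MISSING
        segs = detect_roh(ds, min_snps=30, min_length_bp=1_000_000, max_missing=2)
        assert len(segs) >= 1
        assert max(s.n_missing_used for s in segs) >= 1

    def test_simulator_roh_recovered(self):
        cfg = SimulationConfig(
            seed=8, n_snps=1000, n_chromosomes=2, n_pop1=30, n_pop2=5,
            founder_haplotypes=300, missing_rate=0.0, roh_per_individual=1,
            roh_length_bp=3_000_000, n_outlier_loci=1,
        )
        ds, truth = simulate_dataset(cfg)
        sok = ds.restrict_to_population("SOK")
        segs = detect_roh(sok, min_snps=30, min_length_bp=1_000_000)
        by_sample = {}
        for s in segs:
            by_sample.setdefault(s.sample_id, []).append(s)
        recovered = 0
        total = 0
        for i, sample in enumerate(sok.samples):
            for chrom, start, end in truth.roh_intervals[i]:
                if end - start < 1_500_000:
                    continue
                total += 1
                for s in by_sample.get(sample, []):
                    if s.chromosome != chrom:
                        continue
                    ov = min(end, s.end_bp) - max(start, s.start_bp)
                    if ov >= 0.5 * (end - start) and ov >= 0.5 * s.length_bp:
                        recovered += 1
                        break
        assert total > 0
        assert recovered / total >= 0.9


class TestFroh:
    def test_no_segments_zero(self):
        ds = homozygous_run_dataset()
        assert f_roh([], ds)["ind0"] == 0.0

    def test_full_chromosome_is_one(self):
        d = np.full((1, 50), 2, dtype=np.int8)
        ds = make_dataset(d, positions=[1000 * (j + 1) for j in range(50)])
        segs = detect_roh(ds, min_snps=10, min_length_bp=10_000)
        assert f_roh(segs, ds)["ind0"] == pytest.approx(1.0)

    def test_monotone_in_burden(self):
        vals = []
        for n_roh in (0, 1, 3):
            cfg = SimulationConfig(
                seed=9, n_snps=1500, n_chromosomes=3, n_pop1=20, n_pop2=5,
                founder_haplotypes=400, missing_rate=0.0,
                roh_per_individual=n_roh, roh_length_bp=2_500_000, n_outlier_loci=1,
            )
            ds, _ = simulate_dataset(cfg)
            sok = ds.restrict_to_population("SOK")
            fr = f_roh(detect_roh(sok), sok)
            vals.append(np.mean(list(fr.values())))
        assert vals[0] <= vals[1] <= vals[2]


class TestNeLd:
    def test_zero_corrected_r2_is_infinite(self):
        ne, _ = waples_ne(1.0 / 100 + 3.19 / 100**2, 100.0)
        assert ne == float("inf")

    def test_algebraic_inversion(self):
        # forward relation r2' = 1/(3Ne) - 0.69/Ne^2 derived from the
        # quadratic the estimator inverts (S >= 30 branch)
        for ne_true in (50.0, 100.0, 500.0):
            r2p = 1.0 / (3.0 * ne_true) - 0.69 / ne_true**2
            S = 1000.0
            expect = 1.0 / S + 3.19 / S**2
            ne, _ = waples_ne(r2p + expect, S)
            assert ne == pytest.approx(ne_true, rel=1e-9)

    def test_bottleneck_vs_large_pool_ordering(self):
        nes = []
        for founders in (40, 2000):
            cfg = SimulationConfig(
                seed=9, n_snps=2000, n_pop1=50, n_pop2=5,
                founder_haplotypes=founders, missing_rate=0.0,
                roh_per_individual=0, n_outlier_loci=1,
            )
            ds, _ = simulate_dataset(cfg)
            est = ne_ld(ds.restrict_to_population("SOK"), seed=1)
            nes.append(est.ne)
        assert nes[1] > nes[0]

    def test_single_chromosome_rejected(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.integers(0, 3, size=(40, 30)))
        with pytest.raises(ValueError):
            ne_ld(ds)
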
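import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from divscan import GenotypeDataset, SimulationConfig, SnpRecord, simulate_dataset


def make_dataset(dosages, populations=None, chrom=None, positions=None, alleles=None):
    """Small hand-built dataset; dosages is an (n_samples, n_snps) list/array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    populations = populations or ["P1"] * n
    chrom = chrom or ["1"] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    alleles = alleles or [("A", "B")] * m
    snps = [
        SnpRecord(f"s{j}", chrom[j], positions[j], alleles[j][0], alleles[j][1])
        for j in range(m)
    ]
    return GenotypeDataset(
        samples=[f"ind{i}" for i in range(n)],
        populations=list(populations),
        snps=snps,
        dosages=d,
    )


@pytest.fixture(scope="session")
def two_pop_separated():
    """Two clearly separated populations (FST 0.05) for structure analyses."""
    cfg = SimulationConfig(
        seed=11, n_snps=800, n_pop1=50, n_pop2=40, background_fst=0.05,
        n_outlier_loci=8, outlier_fst=0.3, founder_haplotypes=200,
        missing_rate=0.01, roh_per_individual=0,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def planted_outlier_scan():
    """Default-scale simulation with one planted selection signature."""
    cfg = SimulationConfig(seed=4, missing_rate=0.01, roh_per_individual=0)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
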
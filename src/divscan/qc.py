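"""Marker quality control: call rate, MAF, missingness and per-population HWE.

The filter cascade mirrors standard array QC for a two-breed differentiation
scan: drop markers on excluded (sex) chromosomes, then low call rate, then
low minor allele frequency or excess missingness, then markers out of
Hardy-Weinberg equilibrium in any single population at a stringent exact-test
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeDataset

__all__ = [
    "QcConfig",
    "SnpQcStats",
    "compute_snp_stats",
    "hwe_exact_test",
    "apply_filters",
]


@dataclass
class QcConfig:
    min_call_rate: float = 0.97
    min_maf: float = 0.05
    max_missing: float = 0.20
    hwe_alpha: float = 1.0e-6
    excluded_chromosomes: frozenset[str] = frozenset()

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if not (0.0 <= self.hwe_alpha <= 1.0):
            raise ValueError("hwe_alpha outside [0,1]")


@dataclass
class SnpQcStats:
    snp_id: str
    call_rate: float
    maf: float  # NaN when every genotype is missing
    missing_fraction: float
    hwe_p_per_population: dict[str, float] = field(default_factory=dict)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    count's (the standard SNP exact test).  Returns 1.0 for monomorphic
    tables.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # P(n_het | n_a, n_b, n) for all het counts of the same parity as rare
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_ab)]
    # small relative slack so ties are included despite floating error
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def compute_snp_stats(ds: GenotypeDataset) -> list[SnpQcStats]:
    """Per-SNP call rate, MAF, missing fraction and per-population HWE p."""
    if ds.n_samples < 1:
        raise ValueError("dataset has no samples")
    d = ds.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / ds.n_samples
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs), np.nan)
    maf = np.minimum(p, 1.0 - p)

    pops = ds.population_labels
    hwe: dict[str, np.ndarray] = {}
    for pop in pops:
        m = ds.population_mask(pop)
        sub = d[m]
        n_bb_ = (sub == 0).sum(axis=0)
        n_ab_ = (sub == 1).sum(axis=0)
        n_aa_ = (sub == 2).sum(axis=0)
        hwe[pop] = np.asarray(
            [
                hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else 1.0
                for a, h, b in zip(n_aa_, n_ab_, n_bb_)
            ]
        )
    return [
        SnpQcStats(
            snp_id=snp.snp_id,
            call_rate=float(1.0 - miss_frac[j]),
            maf=float(maf[j]),
            missing_fraction=float(miss_frac[j]),
            hwe_p_per_population={pop: float(hwe[pop][j]) for pop in pops},
        )
        for j, snp in enumerate(ds.snps)
    ]


def apply_filters(
    ds: GenotypeDataset, cfg: QcConfig | None = None
) -> tuple[GenotypeDataset, dict[str, int]]:
    """Apply the QC cascade; returns the filtered dataset and exclusion counts.

    A SNP is removed if it sits on an excluded chromosome, its call rate is
    <= ``min_call_rate``, its MAF is < ``min_maf`` (undefined MAF always
    fails), its missing fraction is >= ``max_missing``, or its exact HWE
    p-value is < ``hwe_alpha`` in any single population.  Counts attribute
    each exclusion to the first criterion that fired, in that order.
    """
    cfg = cfg or QcConfig()
    cfg.validate()
    stats = compute_snp_stats(ds)
    counts = {
        "chromosome": 0,
        "call_rate": 0,
        "maf": 0,
        "missingness": 0,
        "hwe": 0,
        "retained": 0,
    }
    keep: list[int] = []
    for j, (snp, st) in enumerate(zip(ds.snps, stats)):
        if snp.chromosome in cfg.excluded_chromosomes:
            counts["chromosome"] += 1
        elif cfg.min_call_rate > 0 and st.call_rate <= cfg.min_call_rate:
            counts["call_rate"] += 1
        elif np.isnan(st.maf) or st.maf < cfg.min_maf:
            counts["maf"] += 1
        elif cfg.max_missing < 1 and st.missing_fraction >= cfg.max_missing:
            counts["missingness"] += 1
        elif any(p < cfg.hwe_alpha for p in st.hwe_p_per_population.values()):
            counts["hwe"] += 1
        else:
            counts["retained"] += 1
            keep.append(j)
    return ds.subset_snps(keep), counts
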
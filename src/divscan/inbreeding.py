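"""GRM/kinship, genomic inbreeding coefficients, ROH and LD-based Ne.

Four genomic inbreeding measures are computed:

* ``f_grm``  — the variance-standardised self-relationship minus 1
  (diagonal of the GRM minus 1);
* ``f_mom``  — the method-of-moments excess-homozygosity coefficient
  (observed vs expected homozygote count, small-sample corrected);
* ``f_u``    — the coefficient based on the correlation between uniting
  gametes (per-locus quadratic form in the dosage);
* ``f_roh``  — the fraction of the SNP-covered genome lying in runs of
  homozygosity of at least 30 SNPs and more than 1 Mb.

Effective population size is estimated by the LD method: the mean squared
genotypic correlation among unlinked (inter-chromosomal) SNP pairs, reduced
by its finite-sample expectation, inverted through the drift relationship
(Waples & Do correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset

__all__ = [
    "InbreedingReport",
    "RohSegment",
    "NeEstimate",
    "grm",
    "inbreeding_coefficients",
    "detect_roh",
    "f_roh",
    "ne_ld",
    "waples_ne",
]


def waples_ne(r2_mean: float, S: float) -> tuple[float, float]:
    """Invert mean unlinked-pair r2 to Ne (Waples & Do sample correction).

    Returns ``(ne, expectation)`` where expectation is the finite-sample
    E[r2] subtracted before inversion; ``ne`` is inf when the corrected r2
    is <= 0.
    """
    if S >= 30:
        expect = 1.0 / S + 3.19 / S**2
        c1, c2 = 1.0 / 3.0, 2.76
    else:
        expect = 0.0018 + 0.907 / S + 4.44 / S**2
        c1, c2 = 0.618, 5.24
    r2p = r2_mean - expect
    if r2p <= 0:
        return float("inf"), expect
    disc = max(c1**2 - c2 * r2p, 0.0)
    return float((c1 + np.sqrt(disc)) / (2.0 * r2p)), expect


@dataclass
class RohSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het_used: int
    n_missing_used: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class InbreedingReport:
    samples: list[str]
    f_grm: np.ndarray
    f_mom: np.ndarray
    f_u: np.ndarray


@dataclass
class NeEstimate:
    ne: float  # inf when the corrected r2 is <= 0
    r2_mean: float
    r2_sample_correction: float
    n_snps_used: int
    n_pairs_used: int


def _polymorphic(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dosages, obs mask, freqs) over polymorphic loci of the dataset."""
    d = ds.dosages.astype(float)
    obs = ds.dosages != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    keep = (n_obs > 0) & (p > 0) & (p < 1)
    return d[:, keep], obs[:, keep], p[keep]


def grm(ds: GenotypeDataset) -> np.ndarray:
    """Variance-standardised genetic relationship matrix.

    G_ij = mean over jointly genotyped polymorphic loci of
    (d_il - 2p_l)(d_jl - 2p_l) / (2 p_l (1-p_l)), with p_l estimated from
    the analysed samples.  Raises ``ValueError`` for a pair with no joint
    locus.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d, obs, p = _polymorphic(ds)
    z = np.where(obs, (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)), 0.0)
    joint = obs.astype(float) @ obs.astype(float).T
    if np.any(joint == 0):
        i, j = np.argwhere(joint == 0)[0]
        raise ValueError(
            f"samples {ds.samples[i]} and {ds.samples[j]} share no genotyped locus"
        )
    return (z @ z.T) / joint


def inbreeding_coefficients(ds: GenotypeDataset) -> InbreedingReport:
    """The three marker-by-marker inbreeding coefficients per sample.

    Allele frequencies are taken from the analysed dataset itself, so pass
    a single-population subset for per-population reporting.
    """
    d, obs, p = _polymorphic(ds)
    n_l = obs.sum(axis=0).astype(float)

    g = grm(ds)
    fgrm = np.diag(g) - 1.0

    # method-of-moments: (observed hom - expected hom) / (L - expected hom)
    het = 2.0 * p * (1.0 - p) * (2.0 * n_l / (2.0 * n_l - 1.0))
    exp_hom_l = 1.0 - het  # per-locus expected homozygote probability
    obs_hom = np.where(obs, (d != 1.0), False).sum(axis=1).astype(float)
    exp_hom = (obs * exp_hom_l).sum(axis=1)
    L_i = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fmom = (obs_hom - exp_hom) / (L_i - exp_hom)

    # correlation between uniting gametes
    with np.errstate(invalid="ignore"):
        term = (d * d - (1.0 + 2.0 * p) * d + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    fu = np.where(obs, term, 0.0).sum(axis=1) / np.maximum(L_i, 1.0)
    fu = np.where(L_i > 0, fu, np.nan)
    fmom = np.where(L_i > 0, fmom, np.nan)
    return InbreedingReport(
        samples=list(ds.samples), f_grm=fgrm, f_mom=fmom, f_u=fu
    )


def detect_roh(
    ds: GenotypeDataset,
    min_snps: int = 30,
    min_length_bp: int = 1_000_000,
    max_het: int = 0,
    max_missing: int = 2,
) -> list[RohSegment]:
    """Runs of homozygosity per sample, per chromosome.

    A run is a maximal stretch of consecutive markers containing at most
    ``max_het`` heterozygous and ``max_missing`` missing calls; its ends are
    trimmed to homozygous calls.  Reported runs need at least ``min_snps``
    markers and a bp length strictly above ``min_length_bp``.
    """
    chroms = ds.chromosomes()
    pos = ds.positions()
    segments: list[RohSegment] = []
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        p_c = pos[idx]
        for i, sample in enumerate(ds.samples):
            g = ds.dosages[i, idx]
            het = g == 1
            mis = g == MISSING
            m = len(idx)
            best_end = -1
            s = 0
            while s < m:
                if het[s] or mis[s]:
                    s += 1
                    continue
                # extend maximal window starting at s
                nh = nm = 0
                e = s
                last_ok = s
                j = s
                while j < m:
                    if het[j]:
                        if nh + 1 > max_het:
                            break
                        nh += 1
                    elif mis[j]:
                        if nm + 1 > max_missing:
                            break
                        nm += 1
                    else:
                        last_ok = j
                    j += 1
                e = last_ok
                if e > best_end:  # skip windows nested in a previous one
                    best_end = e
                    n_in = e - s + 1
                    seg_het = int(het[s : e + 1].sum())
                    seg_mis = int(mis[s : e + 1].sum())
                    n_hom = n_in - seg_het - seg_mis
                    length = int(p_c[e] - p_c[s])
                    if n_hom + seg_het >= min_snps and length > min_length_bp:
                        segments.append(
                            RohSegment(
                                sample_id=sample,
                                chromosome=str(c),
                                start_bp=int(p_c[s]),
                                end_bp=int(p_c[e]),
                                n_snps=n_in - seg_mis,
                                n_het_used=seg_het,
                                n_missing_used=seg_mis,
                            )
                        )
                s += 1
                # fast-forward past positions that cannot start a longer run
                while s < m and s <= e and (het[s] or mis[s]):
                    s += 1
    return segments


def f_roh(
    segments: list[RohSegment], ds: GenotypeDataset
) -> dict[str, float]:
    """Per-sample fraction of the SNP-covered genome lying in ROH.

    The denominator is the summed per-chromosome span (last SNP bp - first
    SNP bp) of the dataset's map — the genome portion actually covered by
    markers.
    """
    chroms = ds.chromosomes()
    pos = ds.positions()
    covered = 0
    for c in dict.fromkeys(chroms):
        p_c = pos[chroms == c]
        covered += int(p_c.max() - p_c.min())
    if covered <= 0:
        raise ValueError("zero SNP-covered length")
    by_sample: dict[str, dict[str, list[tuple[int, int]]]] = {
        s: {} for s in ds.samples
    }
    for seg in segments:
        by_sample[seg.sample_id].setdefault(seg.chromosome, []).append(
            (seg.start_bp, seg.end_bp)
        )
    out: dict[str, float] = {}
    for s, per_chrom in by_sample.items():
        total = 0
        for ivals in per_chrom.values():
            # merge overlaps so shared stretches are not double-counted
            ivals.sort()
            cur_s, cur_e = ivals[0]
            for a, b in ivals[1:]:
                if a <= cur_e:
                    cur_e = max(cur_e, b)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = a, b
            total += cur_e - cur_s
        out[s] = total / covered
    return out


def ne_ld(
    ds: GenotypeDataset,
    n_snps_sampled: int = 1000,
    maf_min: float = 0.05,
    seed: int = 0,
) -> NeEstimate:
    """LD-based effective population size from unlinked SNP pairs.

    ``n_snps_sampled`` markers with MAF >= ``maf_min`` are drawn at random;
    the squared Pearson correlation of dosages is averaged over all
    inter-chromosomal pairs (computed on jointly genotyped individuals).
    The sample-size expectation E[r2] (1/S + 3.19/S^2 for harmonic mean
    sample size S >= 30, else 0.0018 + 0.907/S + 4.44/S^2) is subtracted
    and the result inverted to Ne; a corrected r2 <= 0 yields infinite Ne.
    """
    chroms = ds.chromosomes()
    if len(set(chroms)) < 2:
        raise ValueError("need >= 2 chromosomes for unlinked pairs")
    rng = np.random.default_rng(seed)
    d = ds.dosages.astype(float)
    obs = ds.dosages != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
        maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero((maf >= maf_min) & (n_obs >= 2))
    take = min(n_snps_sampled, eligible.size)
    sel = np.sort(rng.choice(eligible, size=take, replace=False))

    D = np.where(obs[:, sel], d[:, sel], 0.0)
    M = obs[:, sel].astype(float)
    # pairwise-complete correlation via sufficient statistics
    N = M.T @ M
    Sx = D.T @ M
    Sxx = (D * D).T @ M
    Sxy = D.T @ D
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / N
        varx = Sxx - Sx**2 / N
        r2 = cov**2 / (varx * varx.T)

    cross = chroms[sel][:, None] != chroms[sel][None, :]
    valid = cross & np.isfinite(r2) & (N >= 2)
    iu = np.triu_indices(take, k=1)
    mask = valid[iu]
    r2_vals = r2[iu][mask]
    n_vals = N[iu][mask]
    if r2_vals.size == 0:
        raise ValueError("no informative unlinked pairs")
    r2_mean = float(r2_vals.mean())
    S = float(r2_vals.size / np.sum(1.0 / n_vals))  # harmonic mean sample size
    ne, expect = waples_ne(r2_mean, S)
    return NeEstimate(
        ne=float(ne),
        r2_mean=r2_mean,
        r2_sample_correction=float(expect),
        n_snps_used=int(take),
        n_pairs_used=int(r2_vals.size),
    )
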
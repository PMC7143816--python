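"""Pairwise linkage disequilibrium and Gabriel haplotype blocks.

Haplotype frequencies for a pair of unphased biallelic SNPs are estimated by
the classic two-locus EM (only the double-heterozygote class is phase
ambiguous).  D' and r2 follow from the estimated frequencies; a confidence
interval on D' is obtained from the normalised likelihood on a 101-point
grid (the approach of the standard haplotype-browser tool), and blocks are
called with the Gabriel confidence-interval rules: a pair is in "strong LD"
when its D' CI is [>=0.70, >=0.98], shows "strong recombination" when the
CI upper bound is <0.90, and a block is an interval whose outermost pair is
in strong LD and whose informative pairs are >=95% strong-LD.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .io import MISSING, GenotypeDataset

__all__ = [
    "PairLd",
    "HaplotypeBlock",
    "genotype_pair_counts",
    "two_locus_em",
    "dprime_r2",
    "dprime_ci",
    "pairwise_ld",
    "gabriel_blocks",
    "block_haplotypes",
]

_EM_TOL = 1e-9
_EM_MAX_ITER = 1000
_CI_GRID = 101
# Gabriel-rule thresholds (published defaults of the cited block method)
_STRONG_LD_LOW = 0.70
_STRONG_LD_HIGH = 0.98
_RECOMB_HIGH = 0.90
_STRONG_FRACTION = 0.95
_MIN_INFORMATIVE_CHROMS = 20
_INFORMATIVE_MAF = 0.05


@dataclass
class PairLd:
    snp_i: int  # indices into the analysed SNP list
    snp_j: int
    distance_bp: int
    haplotype_freqs: tuple[float, float, float, float]  # AB, Ab, aB, ab
    d_prime: float
    r2: float
    d_prime_ci: tuple[float, float]
    n_informative: int  # chromosomes (2 x jointly genotyped diploids)
    informative: bool = True


@dataclass
class HaplotypeBlock:
    chromosome: str
    first_snp_index: int
    last_snp_index: int
    haplotypes: list[tuple[str, float]]

    @property
    def n_snps(self) -> int:
        return self.last_snp_index - self.first_snp_index + 1


def genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts (rows: dosage at locus 1, cols: locus 2)."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1[ok].astype(int), g2[ok].astype(int)), 1)
    return counts


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 9 genotype classes given hap freqs.

    ``f`` = (f_AB, f_Ab, f_aB, f_ab) with A/a the counted/other allele at
    locus 1 and B/b at locus 2; dosage 2 at locus 1 means genotype AA.
    """
    fAB, fAb, faB, fab = f
    # genotype-class probabilities: product of two gamete draws
    cls = np.empty((3, 3))
    cls[2, 2] = fAB * fAB
    cls[2, 1] = 2 * fAB * fAb
    cls[2, 0] = fAb * fAb
    cls[1, 2] = 2 * fAB * faB
    cls[1, 1] = 2 * (fAB * fab + fAb * faB)
    cls[1, 0] = 2 * fAb * fab
    cls[0, 2] = faB * faB
    cls[0, 1] = 2 * faB * fab
    cls[0, 0] = fab * fab
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, np.log(np.maximum(cls, 1e-300)), 0.0)
    return float((counts * lp).sum())


def two_locus_em(counts: np.ndarray) -> np.ndarray:
    """ML haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) by EM.

    ``counts`` is the 3x3 joint dosage table.  Initialised at linkage
    equilibrium; iterated until the largest frequency change is < 1e-9 or
    1000 iterations.  Raises ``ValueError`` when no non-missing pair exists.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("no jointly genotyped individuals")
    two_n = 2.0 * n
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / two_n
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / two_n
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    # unambiguous gamete counts
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # AB
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],  # Ab
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # aB
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # ab
        ],
        dtype=float,
    )
    for _ in range(_EM_MAX_ITER):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        w = coupling / tot if tot > 0 else 0.5
        new = base + dh * np.array([w, 1 - w, 1 - w, w])
        new /= two_n
        if np.max(np.abs(new - f)) < _EM_TOL:
            f = new
            break
        f = new
    return f


def dprime_r2(
    haplotype_freqs: np.ndarray | tuple[float, float, float, float],
) -> tuple[float, float]:
    """Normalised LD coefficient D' and squared correlation r2.

    D = f_AB - pA*pB; D' = |D|/Dmax with Dmax depending on D's sign;
    r2 = D^2 / (pA(1-pA) pB(1-pB)).  Raises ``ValueError`` when either
    locus is monomorphic (LD undefined).
    """
    fAB, fAb, faB, fab = haplotype_freqs
    pA = fAB + fAb
    pB = fAB + faB
    if min(pA, 1 - pA, pB, 1 - pB) <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    D = fAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return float(min(d_prime, 1.0)), float(min(r2, 1.0))


def dprime_ci(counts: np.ndarray) -> tuple[float, float]:
    """90% confidence interval on D' from the normalised likelihood grid.

    The likelihood of the genotype table is evaluated at 101 equally spaced
    values of D' in [0,1] (allele frequencies and the sign of D held at
    their MLEs), normalised to a distribution under a flat prior; the
    interval is its 5th and 95th percentiles.
    """
    counts = np.asarray(counts, dtype=float)
    f_mle = two_locus_em(counts)
    pA = f_mle[0] + f_mle[1]
    pB = f_mle[0] + f_mle[2]
    if min(pA, 1 - pA, pB, 1 - pB) <= 0:
        raise ValueError("monomorphic locus: D' undefined")
    D_mle = f_mle[0] - pA * pB
    if D_mle >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    grid = np.linspace(0.0, 1.0, _CI_GRID)
    ll = np.empty(_CI_GRID)
    for i, dp in enumerate(grid):
        D = sign * dp * dmax
        f = np.array(
            [
                pA * pB + D,
                pA * (1 - pB) - D,
                (1 - pA) * pB - D,
                (1 - pA) * (1 - pB) + D,
            ]
        )
        f = np.clip(f, 0.0, 1.0)
        ll[i] = _loglik(counts, f)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    cdf = np.cumsum(post)
    low = float(grid[int(np.searchsorted(cdf, 0.05))])
    high = float(grid[int(np.searchsorted(cdf, 0.95))])
    return low, high


def pairwise_ld(
    ds: GenotypeDataset,
    snp_indices: list[int] | np.ndarray | None = None,
    max_distance_bp: int = 500_000,
    with_ci: bool = True,
) -> list[PairLd]:
    """All within-chromosome SNP pairs up to ``max_distance_bp`` apart.

    A pair is flagged informative when both SNPs have MAF >= 0.05 and at
    least 20 informative chromosomes (10 jointly genotyped diploids);
    monomorphic pairs are flagged uninformative with NaN statistics.
    """
    if snp_indices is None:
        snp_indices = np.arange(ds.n_snps)
    snp_indices = np.asarray(snp_indices)
    pos = ds.positions()
    chroms = ds.chromosomes()
    out: list[PairLd] = []
    for ii, jj in combinations(range(len(snp_indices)), 2):
        gi, gj = snp_indices[ii], snp_indices[jj]
        if chroms[gi] != chroms[gj]:
            continue
        dist = int(abs(pos[gj] - pos[gi]))
        if dist > max_distance_bp:
            continue
        counts = genotype_pair_counts(ds.dosages[:, gi], ds.dosages[:, gj])
        n = int(counts.sum())
        try:
            f = two_locus_em(counts)
            dp, r2 = dprime_r2(f)
            ci = dprime_ci(counts) if with_ci else (float("nan"), float("nan"))
        except ValueError:
            out.append(
                PairLd(ii, jj, dist, (np.nan,) * 4, np.nan, np.nan,
                       (np.nan, np.nan), 2 * n, informative=False)
            )
            continue
        two_n = 2.0 * counts.sum()
        pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / two_n
        pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / two_n
        informative = (
            min(pA, 1 - pA) >= _INFORMATIVE_MAF
            and min(pB, 1 - pB) >= _INFORMATIVE_MAF
            and 2 * n >= _MIN_INFORMATIVE_CHROMS
        )
        out.append(
            PairLd(ii, jj, dist, tuple(float(x) for x in f), dp, r2, ci,
                   2 * n, informative=informative)
        )
    return out


def gabriel_blocks(
    pairwise: list[PairLd],
    ds: GenotypeDataset,
    snp_indices: list[int] | np.ndarray | None = None,
    max_distance_bp: int = 500_000,
) -> list[HaplotypeBlock]:
    """Call haplotype blocks from pairwise D' confidence intervals.

    Candidate intervals [i..j] require the outermost pair (i, j) to be in
    strong LD and >=95% of informative inner pairs to be strong-LD rather
    than strong-recombination; blocks are selected greedily by descending
    SNP span, keeping non-overlapping intervals, and each block's haplotype
    inventory is attached.
    """
    if snp_indices is None:
        snp_indices = np.arange(ds.n_snps)
    snp_indices = np.asarray(snp_indices)
    m = len(snp_indices)
    chroms = ds.chromosomes()

    strong = {}
    recomb = {}
    informative = {}
    for p in pairwise:
        key = (p.snp_i, p.snp_j)
        informative[key] = p.informative
        if not p.informative:
            continue
        lo, hi = p.d_prime_ci
        strong[key] = lo >= _STRONG_LD_LOW and hi >= _STRONG_LD_HIGH
        recomb[key] = hi < _RECOMB_HIGH

    candidates: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(i + 1, m):
            key = (i, j)
            if chroms[snp_indices[i]] != chroms[snp_indices[j]]:
                continue
            if key not in strong or not strong[key]:
                continue
            n_strong = n_recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    kk = (a, b)
                    if not informative.get(kk, False):
                        continue
                    if strong.get(kk, False):
                        n_strong += 1
                    elif recomb.get(kk, False):
                        n_recomb += 1
            if n_strong == 0:
                continue
            if n_strong / (n_strong + n_recomb) >= _STRONG_FRACTION:
                candidates.append((i, j))

    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken = np.zeros(m, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        block = HaplotypeBlock(
            chromosome=str(chroms[snp_indices[i]]),
            first_snp_index=i,
            last_snp_index=j,
            haplotypes=[],
        )
        block.haplotypes = block_haplotypes(ds, block, snp_indices)
        blocks.append(block)
    blocks.sort(key=lambda b: b.first_snp_index)
    return blocks


def _multi_em(geno: np.ndarray, n_snps: int) -> dict[tuple[int, ...], float]:
    """Multilocus haplotype frequencies by EM with full phase enumeration.

    ``geno``: (individuals, n_snps) dosages without missing entries.
    Returns a dict haplotype-tuple -> frequency.
    """
    # per individual: list of compatible (hap1, hap2) pairs
    resolutions: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = []
    for row in geno:
        het = [i for i in range(n_snps) if row[i] == 1]
        base1 = [1 if row[i] == 2 else 0 for i in range(n_snps)]
        base2 = list(base1)
        pairs = []
        if het:
            for bits in product((0, 1), repeat=len(het) - 1):
                h1 = list(base1)
                h2 = list(base2)
                h1[het[0]], h2[het[0]] = 1, 0
                for hpos, bit in zip(het[1:], bits):
                    h1[hpos], h2[hpos] = bit, 1 - bit
                pairs.append((tuple(h1), tuple(h2)))
        else:
            pairs.append((tuple(base1), tuple(base2)))
        resolutions.append(pairs)

    haps = sorted({h for pairs in resolutions for pr in pairs for h in pr})
    idx = {h: i for i, h in enumerate(haps)}
    f = np.full(len(haps), 1.0 / len(haps))
    two_n = 2.0 * len(resolutions)
    for _ in range(_EM_MAX_ITER):
        new = np.zeros_like(f)
        for pairs in resolutions:
            w = np.array([f[idx[h1]] * f[idx[h2]] for h1, h2 in pairs])
            tot = w.sum()
            w = w / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
            for (h1, h2), wi in zip(pairs, w):
                new[idx[h1]] += wi
                new[idx[h2]] += wi
        new /= two_n
        if np.max(np.abs(new - f)) < _EM_TOL:
            f = new
            break
        f = new
    return {h: float(f[idx[h]]) for h in haps}


def block_haplotypes(
    ds: GenotypeDataset,
    block: HaplotypeBlock,
    snp_indices: list[int] | np.ndarray | None = None,
    min_freq: float = 0.01,
    enumeration_bound: int = 12,
) -> list[tuple[str, float]]:
    """Haplotype inventory of a block: (allele string, frequency), descending.

    Phase is resolved by EM with full enumeration for blocks of up to
    ``enumeration_bound`` SNPs; longer blocks fall back to
    partition-and-ligate EM (halve, solve, ligate the surviving haplotypes).
    Individuals missing a call inside the block are excluded.  Haplotypes
    below ``min_freq`` are truncated, so frequencies sum to <= 1.
    """
    if snp_indices is None:
        snp_indices = np.arange(ds.n_snps)
    snp_indices = np.asarray(snp_indices)
    cols = snp_indices[block.first_snp_index : block.last_snp_index + 1]
    geno = ds.dosages[:, cols]
    geno = geno[(geno != MISSING).all(axis=1)]
    if geno.shape[0] == 0:
        return []
    n_snps = len(cols)
    freqs = _pl_em(geno, n_snps, enumeration_bound)
    alleles = [(ds.snps[c].allele_a, ds.snps[c].allele_b) for c in cols]
    out = [
        ("".join(alleles[i][0] if h[i] else alleles[i][1] for i in range(n_snps)), fr)
        for h, fr in freqs.items()
        if fr >= min_freq
    ]
    out.sort(key=lambda t: -t[1])
    return out


def _pl_em(
    geno: np.ndarray, n_snps: int, bound: int
) -> dict[tuple[int, ...], float]:
    """Partition-and-ligate wrapper around :func:`_multi_em`."""
    if n_snps <= bound:
        return _multi_em(geno, n_snps)
    half = n_snps // 2
    left = _pl_em(geno[:, :half], half, bound)
    right = _pl_em(geno[:, half:], n_snps - half, bound)
    keep_l = sorted(left, key=left.get, reverse=True)[:20]
    keep_r = sorted(right, key=right.get, reverse=True)[:20]
    # ligation EM over the cross-product of surviving partial haplotypes
    haps = [l + r for l in keep_l for r in keep_r]
    idx = {h: i for i, h in enumerate(haps)}
    f = np.array([left[l] * right[r] for l in keep_l for r in keep_r])
    f = f / f.sum() if f.sum() > 0 else np.full(len(haps), 1.0 / len(haps))
    resolutions = []
    for row in geno:
        pairs = []
        for h1 in haps:
            for h2 in haps:
                if all(h1[i] + h2[i] == row[i] for i in range(n_snps)):
                    pairs.append((h1, h2))
        if pairs:
            resolutions.append(pairs)
    if not resolutions:
        return {h: float(fr) for h, fr in zip(haps, f)}
    two_n = 2.0 * len(resolutions)
    for _ in range(200):
        new = np.zeros_like(f)
        for pairs in resolutions:
            w = np.array([f[idx[h1]] * f[idx[h2]] for h1, h2 in pairs])
            tot = w.sum()
            w = w / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
            for (h1, h2), wi in zip(pairs, w):
                new[idx[h1]] += wi
                new[idx[h2]] += wi
        new /= two_n
        if np.max(np.abs(new - f)) < 1e-6:
            f = new
            break
        f = new
    return {h: float(fr) for h, fr in zip(haps, f)}
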
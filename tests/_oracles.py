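"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written from the defining formula or by direct
enumeration, deliberately avoiding the code paths in the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def wc_components_exact(n1, c1_counts, n2, c2_counts):
    """Weir-Cockerham (a, b, c) in exact rational arithmetic.

    ``c*_counts`` are (n_hom_other, n_het, n_hom_counted) genotype counts per
    population; n* are the diploid totals (must match the count sums).
    """
    def stats(n, counts):
        n0, n1h, n2h = counts
        assert n0 + n1h + n2h == n
        p = Fraction(2 * n2h + n1h, 2 * n)
        h = Fraction(n1h, n)
        return Fraction(n), p, h

    N1, p1, h1 = stats(n1, c1_counts)
    N2, p2, h2 = stats(n2, c2_counts)
    r = Fraction(2)
    nbar = (N1 + N2) / r
    nc = (r * nbar - (N1 * N1 + N2 * N2) / (r * nbar)) / (r - 1)
    pbar = (N1 * p1 + N2 * p2) / (r * nbar)
    s2 = (N1 * (p1 - pbar) ** 2 + N2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (N1 * h1 + N2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def hwe_exact_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full rational enumeration of heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs: dict[int, Fraction] = {}
    denom = Fraction(0)
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            continue
        # multinomial count of genotype configurations x 2^het phasings
        weight = Fraction(
            comb(n, het) * comb(n - het, hom_r) * 2**het
        )
        probs[het] = weight
        denom += weight
    probs = {k: v / denom for k, v in probs.items()}
    obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= obs))


def window_means_bruteforce(fst, chroms, window_size):
    """Re-average FST in windows by an explicit double loop."""
    out = []
    chroms = list(chroms)
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(chroms):
        by_chrom.setdefault(c, []).append(i)
    for c, idx in by_chrom.items():
        for s in range(len(idx) - window_size + 1):
            vals = [fst[i] for i in idx[s : s + window_size] if np.isfinite(fst[i])]
            if vals:
                out.append(sum(vals) / len(vals))
    return out


def qvalues_bruteforce(pip):
    """q-value per locus: mean (1 - pip) over loci with pip >= this locus's."""
    pip = np.asarray(pip, dtype=float)
    q = np.empty_like(pip)
    for i, v in enumerate(pip):
        sel = pip >= v
        q[i] = np.mean(1.0 - pip[sel])
    return q


def grm_bruteforce(dosages, missing=-1):
    """GRM by explicit per-pair double loop over jointly observed loci."""
    d = np.asarray(dosages, dtype=float)
    n, L = d.shape
    obs = dosages != missing
    p = np.array(
        [
            d[obs[:, l], l].sum() / (2 * obs[:, l].sum()) if obs[:, l].any() else np.nan
            for l in range(L)
        ]
    )
    keep = [l for l in range(L) if obs[:, l].any() and 0 < p[l] < 1]
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            cnt = 0
            for l in keep:
                if obs[i, l] and obs[j, l]:
                    num += (
                        (d[i, l] - 2 * p[l])
                        * (d[j, l] - 2 * p[l])
                        / (2 * p[l] * (1 - p[l]))
                    )
                    cnt += 1
            G[i, j] = num / cnt
    return G


def em_grid_loglik(counts, f_ab):
    """Genotype-table log-likelihood at a given f_AB (other freqs implied)."""
    counts = np.asarray(counts, dtype=float)
    two_n = 2 * counts.sum()
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / two_n
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / two_n
    fAB = f_ab
    fAb = pA - fAB
    faB = pB - fAB
    fab = 1 - pA - pB + fAB
    if min(fAB, fAb, faB, fab) < -1e-12:
        return -np.inf
    f = np.clip([fAB, fAb, faB, fab], 0, 1)
    cls = np.array(
        [
            [f[3] ** 2, 2 * f[2] * f[3], f[2] ** 2],
            [2 * f[1] * f[3], 2 * (f[0] * f[3] + f[1] * f[2]), 2 * f[0] * f[2]],
            [f[1] ** 2, 2 * f[0] * f[1], f[0] ** 2],
        ]
    )
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, np.log(np.maximum(cls, 1e-300)), 0.0)
    return float((counts * lp).sum())


def additive_distance_from_tree(edges, leaves):
    """Leaf-to-leaf path-length matrix of a tree given as (u, v, length)."""
    import networkx as nx

    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    n = len(leaves)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = nx.shortest_path_length(
                g, leaves[i], leaves[j], weight="weight"
            )
    return dm
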
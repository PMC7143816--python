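"""Weir-Cockerham FST, sliding-window selection scan and candidate regions.

Per-locus differentiation between two populations is measured with the
Weir & Cockerham (1984) variance-component estimator: components ``a``
(between populations), ``b`` (between individuals within populations) and
``c`` (within individuals), with theta-hat = a/(a+b+c).  Window averaging
over 10 consecutive SNPs smooths locus-to-locus sampling noise; windows
above an empirical quantile of the window means are merged into candidate
regions of diversifying selection and extended by 25 kb on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset, SnpRecord

__all__ = [
    "LocusFst",
    "WindowFst",
    "SelectionRegion",
    "wc_components",
    "per_locus_fst",
    "summary_fst",
    "sliding_window_scan",
    "empirical_threshold",
    "build_regions",
]


@dataclass
class LocusFst:
    snp_id: str
    a: float
    b: float
    c: float

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


@dataclass
class WindowFst:
    chromosome: str
    snp_indices: tuple[int, ...]  # global indices of member SNPs
    start_bp: int  # position of first member SNP
    end_bp: int  # position of last member SNP
    mean_fst: float

    @property
    def center_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass
class SelectionRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_window_fst: float
    n_windows_merged: int

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


def wc_components(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float]:
    """Weir-Cockerham variance components for one biallelic locus, two demes.

    Parameters are, per population: ``n`` the number of genotyped diploids,
    ``p`` the counted-allele frequency and ``h`` the observed heterozygote
    fraction.  Returns ``(a, b, c)``; theta-hat = a/(a+b+c).
    """
    if min(n1, n2) < 2:
        return (float("nan"),) * 3
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - s2 * (r - 1.0) / r
        - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return float(a), float(b), float(c)


def _pop_locus_stats(
    ds: GenotypeDataset, label: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) arrays over loci for one population, missing excluded."""
    d = ds.dosages[ds.population_mask(label)]
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
        h = (d == 1).sum(axis=0) / n
    return n, p, h


def per_locus_fst(
    ds: GenotypeDataset, pops: tuple[str, str] | None = None
) -> list[LocusFst]:
    """Weir-Cockerham components at every SNP, in map order.

    ``pops`` selects the two populations to contrast; it may be omitted only
    when the dataset carries exactly two labels.
    """
    labels = ds.population_labels
    if pops is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two populations, found {labels}")
        pops = (labels[0], labels[1])
    if len(set(pops)) != 2 or any(p not in labels for p in pops):
        raise ValueError(f"invalid population pair {pops} for labels {labels}")
    n1, p1, h1 = _pop_locus_stats(ds, pops[0])
    n2, p2, h2 = _pop_locus_stats(ds, pops[1])
    # vectorised transcription of wc_components
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return [
        LocusFst(snp.snp_id, float(a[j]), float(b[j]), float(c[j]))
        for j, snp in enumerate(ds.snps)
    ]


def summary_fst(loci: list[LocusFst]) -> tuple[float, float]:
    """Genome-wide (mean, weighted mean) FST.

    Mean is the average of per-locus ratios over loci with a defined ratio;
    the weighted mean is the ratio of sums, sum(a)/sum(a+b+c), over the same
    loci.
    """
    a = np.asarray([l.a for l in loci])
    denom = np.asarray([l.a + l.b + l.c for l in loci])
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        raise ValueError("no locus with a defined FST")
    mean = float(np.mean(a[ok] / denom[ok]))
    weighted = float(a[ok].sum() / denom[ok].sum())
    return mean, weighted


def sliding_window_scan(
    loci: list[LocusFst],
    snps: list[SnpRecord],
    window_size: int = 10,
    step: int = 1,
) -> list[WindowFst]:
    """Average per-locus FST in windows of ``window_size`` consecutive SNPs.

    Windows never span chromosomes; the mean is over the window's non-NaN
    loci and a window with no defined locus is dropped.  Chromosomes shorter
    than one window contribute no windows.
    """
    if len(loci) != len(snps):
        raise ValueError("loci and map lengths differ")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    fst = np.asarray([l.fst for l in loci])
    chroms = np.asarray([s.chromosome for s in snps], dtype=object)
    pos = np.asarray([s.position_bp for s in snps], dtype=np.int64)
    windows: list[WindowFst] = []
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        for s0 in range(0, len(idx) - window_size + 1, step):
            member = idx[s0 : s0 + window_size]
            vals = fst[member]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            windows.append(
                WindowFst(
                    chromosome=str(c),
                    snp_indices=tuple(int(i) for i in member),
                    start_bp=int(pos[member[0]]),
                    end_bp=int(pos[member[-1]]),
                    mean_fst=float(vals.mean()),
                )
            )
    return windows


def empirical_threshold(windows: list[WindowFst], quantile: float = 0.999) -> float:
    """Empirical order-statistic quantile of the window means.

    Windows whose mean is strictly greater than the returned threshold are
    selection-signature candidates.
    """
    if not windows:
        raise ValueError("no windows")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0,1)")
    means = np.sort([w.mean_fst for w in windows])
    k = int(np.ceil(quantile * means.size)) - 1
    return float(means[max(k, 0)])


def build_regions(
    candidates: list[WindowFst],
    extension_bp: int = 25_000,
) -> list[SelectionRegion]:
    """Merge overlapping candidate windows into extended selection regions.

    Windows on the same chromosome sharing any SNP or overlapping in bp are
    merged; the merged span runs from the smallest first-SNP position to the
    largest last-SNP position, then each side is extended by ``extension_bp``
    (start floored at 1).  Region size is ``end - start``.
    """
    regions: list[SelectionRegion] = []
    by_chrom: dict[str, list[WindowFst]] = {}
    for w in candidates:
        by_chrom.setdefault(w.chromosome, []).append(w)
    for chrom, wins in by_chrom.items():
        wins = sorted(wins, key=lambda w: (w.start_bp, w.end_bp))
        cur = [wins[0]]
        cur_snps = set(wins[0].snp_indices)
        cur_end = wins[0].end_bp

        def flush(group: list[WindowFst]) -> None:
            start = min(w.start_bp for w in group) - extension_bp
            end = max(w.end_bp for w in group) + extension_bp
            regions.append(
                SelectionRegion(
                    chromosome=chrom,
                    start_bp=max(1, start),
                    end_bp=end,
                    peak_window_fst=max(w.mean_fst for w in group),
                    n_windows_merged=len(group),
                )
            )

        for w in wins[1:]:
            if w.start_bp <= cur_end or cur_snps & set(w.snp_indices):
                cur.append(w)
                cur_snps |= set(w.snp_indices)
                cur_end = max(cur_end, w.end_bp)
            else:
                flush(cur)
                cur = [w]
                cur_snps = set(w.snp_indices)
                cur_end = w.end_bp
        flush(cur)
    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    return regions
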
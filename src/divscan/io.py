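"""Genotype data model and PLINK PED/MAP & VCF readers/writers.

The universal container is :class:`GenotypeDataset`: an individuals x SNP
matrix of allele dosages in {0, 1, 2, MISSING} counting copies of each SNP's
``allele_a``, plus a genetic map (chromosome, bp position) and a population
label per sample.  Coordinates are 1-based inclusive throughout (PLINK/VCF
convention).

Allele orientation in PED files is inherently data-dependent: PED carries no
REF/ALT designation, so on read the counted allele ``allele_a`` is the first
non-missing allele encountered in the SNP's genotype column.  Every
differentiation statistic downstream (MAF, HWE, FST, D', r2) is invariant to
this choice; dosages themselves are not, and :func:`harmonize_alleles` flips
a dataset onto a reference orientation when exact dosage agreement matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeDataset",
    "GenotypeFormatError",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
    "validate_dataset",
    "harmonize_alleles",
]

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


class GenotypeFormatError(ValueError):
    """Raised for malformed PED/MAP/VCF content."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identity, map position and allele labels.

    ``allele_a`` is the counted allele (dosage = number of its copies);
    ``allele_b`` is the other allele.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for a set of samples.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    populations
        Population label per sample, aligned with ``samples``.
    snps
        SNP records sorted by (chromosome, position) in map order.
    dosages
        ``(n_samples, n_snps)`` int8 matrix with entries in
        ``{0, 1, 2, MISSING}`` counting ``allele_a`` copies.
    """

    samples: list[str]
    populations: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_mask(self, label: str) -> np.ndarray:
        return np.asarray([p == label for p in self.populations], dtype=bool)

    def positions(self) -> np.ndarray:
        return np.asarray([s.position_bp for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.asarray([s.chromosome for s in self.snps], dtype=object)

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=list(self.samples),
            populations=list(self.populations),
            snps=[self.snps[i] for i in index],
            dosages=self.dosages[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=[self.samples[i] for i in index],
            populations=[self.populations[i] for i in index],
            snps=list(self.snps),
            dosages=self.dosages[index, :].copy(),
        )

    def restrict_to_population(self, label: str) -> "GenotypeDataset":
        return self.subset_samples(self.population_mask(label))


def validate_dataset(ds: GenotypeDataset) -> list[str]:
    """Return one message per violated dataset invariant (empty list if valid)."""
    messages: list[str] = []
    ids = [s.snp_id for s in ds.snps]
    if len(set(ids)) != len(ids):
        messages.append("duplicate SNP ids present")
    for snp in ds.snps:
        if snp.position_bp < 1:
            messages.append(f"SNP {snp.snp_id}: position {snp.position_bp} < 1")
        if snp.allele_a == snp.allele_b:
            messages.append(f"SNP {snp.snp_id}: allele_a equals allele_b")
    # map must be strictly increasing within each chromosome
    last: dict[str, tuple[int, str]] = {}
    for snp in ds.snps:
        if snp.chromosome in last and snp.position_bp <= last[snp.chromosome][0]:
            messages.append(
                f"unsorted map: SNP {snp.snp_id} at {snp.chromosome}:"
                f"{snp.position_bp} not after {last[snp.chromosome][1]}"
            )
        last[snp.chromosome] = (snp.position_bp, snp.snp_id)
    bad = ~np.isin(ds.dosages, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        messages.append(
            f"invalid dosage {int(ds.dosages[i, j])} at sample "
            f"{ds.samples[i]}, SNP {ds.snps[j].snp_id}"
        )
    if not ds.populations:
        messages.append("no population labels present")
    return messages


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read whitespace-delimited PLINK text PED/MAP into a dataset.

    The PED family-ID column is taken as the population label.  "0 0" allele
    pairs decode to MISSING.  The counted allele of each SNP is the first
    non-missing allele encountered in its column.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeFormatError(f"{map_path}:{ln}: expected 4 MAP columns")
            chrom, snp_id, _cm, bp = parts[:4]
            map_rows.append((chrom, snp_id, int(bp)))
    n_snps = len(map_rows)

    samples: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields for "
                    f"{n_snps} MAP SNPs, found {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            populations.append(fam)
            samples.append(iid)
            allele_rows.append(parts[6:])

    n_samples = len(samples)
    dosages = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    for j, (chrom, snp_id, bp) in enumerate(map_rows):
        a_allele: str | None = None
        b_allele: str | None = None
        for i in range(n_samples):
            x, y = allele_rows[i][2 * j], allele_rows[i][2 * j + 1]
            if x == "0" or y == "0":
                if x != y:
                    raise GenotypeFormatError(
                        f"SNP {snp_id}, sample {samples[i]}: half-missing genotype"
                    )
                continue
            for al in (x, y):
                if a_allele is None:
                    a_allele = al
                elif al != a_allele and b_allele is None:
                    b_allele = al
                elif al not in (a_allele, b_allele):
                    raise GenotypeFormatError(
                        f"SNP {snp_id} is not biallelic: saw alleles "
                        f"{{{a_allele}, {b_allele}, {al}}}"
                    )
            dosages[i, j] = (x == a_allele) + (y == a_allele)
        if a_allele is None:  # fully missing column
            a_allele, b_allele = "A", "B"
        if b_allele is None:
            b_allele = "B" if a_allele != "B" else "A"
        snps.append(SnpRecord(snp_id, chrom, bp, a_allele, b_allele))
    return GenotypeDataset(samples, populations, snps, dosages)


def write_ped_map(
    ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as PLINK text PED/MAP (population label = family ID)."""
    with open(map_path, "w") as fh:
        for snp in ds.snps:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position_bp}\n")
    code = {
        2: lambda s: (s.allele_a, s.allele_a),
        1: lambda s: (s.allele_a, s.allele_b),
        0: lambda s: (s.allele_b, s.allele_b),
        MISSING: lambda s: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for i, (iid, pop) in enumerate(zip(ds.samples, ds.populations)):
            fields = [pop, iid, "0", "0", "0", "-9"]
            for j, snp in enumerate(ds.snps):
                fields.extend(code[int(ds.dosages[i, j])](snp))
            fh.write(" ".join(fields) + "\n")


def harmonize_alleles(ds: GenotypeDataset, reference: GenotypeDataset) -> GenotypeDataset:
    """Flip SNP orientations of ``ds`` to match ``reference``'s counted alleles.

    SNPs are matched by id; a SNP whose allele labels cannot be reconciled
    with the reference raises :class:`GenotypeFormatError`.
    """
    ref = {s.snp_id: s for s in reference.snps}
    snps: list[SnpRecord] = []
    dosages = ds.dosages.copy()
    for j, snp in enumerate(ds.snps):
        r = ref.get(snp.snp_id)
        if r is None:
            snps.append(snp)
            continue
        if snp.allele_a == r.allele_a:
            snps.append(snp)
        elif snp.allele_a == r.allele_b or {snp.allele_a, snp.allele_b} == {"A", "B"}:
            # flip orientation; fully-missing/monomorphic columns read back with
            # placeholder labels and adopt the reference orientation unchanged
            if snp.allele_a == r.allele_b:
                col = dosages[:, j]
                obs = col != MISSING
                dosages[obs, j] = 2 - col[obs]
            snps.append(r)
        else:
            raise GenotypeFormatError(
                f"SNP {snp.snp_id}: alleles {snp.allele_a}/{snp.allele_b} "
                f"irreconcilable with reference {r.allele_a}/{r.allele_b}"
            )
    return GenotypeDataset(list(ds.samples), list(ds.populations), snps, dosages)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    vcf_path: str | Path, pop_labels: Mapping[str, str]
) -> tuple[GenotypeDataset, int]:
    """Read biallelic SNP records from a VCF (GT field only).

    REF is ``allele_b``, ALT is ``allele_a`` (dosage = ALT allele count);
    ``./.`` decodes to MISSING.  Non-biallelic records are skipped and
    counted.  Returns ``(dataset, n_skipped)``.

    Raises ``KeyError`` listing any VCF sample absent from ``pop_labels``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_labels]
    if unknown:
        raise KeyError(f"samples missing from population table: {unknown}")
    populations = [pop_labels[s] for s in samples]

    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        snps.append(
            SnpRecord(
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM),
                int(var.POS),
                allele_a=var.ALT[0],
                allele_b=var.REF,
            )
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    dosages = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(samples, populations, snps, dosages)
    return ds, n_skipped
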
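"""End-to-end orchestration of the two-population differentiation analysis.

Stage order follows the study workflow: ingest (or simulate) genotypes, QC,
per-SNP FST with the sliding-window scan and region construction, Bayesian
verification of the candidate loci, population-structure analyses,
inbreeding and effective population size per population, and region-local
haplotype-block analysis.  All stochastic stages derive their seeds from the
single pipeline seed, so a re-run with the same configuration is
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayescan import BayesModelConfig, posterior_outliers, rjmcmc_run
from .fst import (
    build_regions,
    empirical_threshold,
    per_locus_fst,
    sliding_window_scan,
    summary_fst,
)
from .inbreeding import detect_roh, f_roh, inbreeding_coefficients, ne_ld
from .io import GenotypeDataset, read_ped_map
from .ld import gabriel_blocks, pairwise_ld
from .qc import QcConfig, apply_filters
from .simulate import SimulationConfig, simulate_dataset
from .structure import admixture_cv, ibs_distance, nj_tree, pca

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "consolidate_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; seed is propagated to every stage."""

    seed: int = 0
    input_prefix: str | None = None  # read <prefix>.ped/.map; else simulate
    simulation: SimulationConfig | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    window_size: int = 10
    quantile: float = 0.999
    extension_bp: int = 25_000
    bayes: BayesModelConfig | None = None
    bayes_alpha_level: float = 0.05
    k_range: tuple[int, int] = (1, 5)
    cv_folds: int = 5
    n_pca_components: int = 10
    roh_min_snps: int = 30
    roh_min_length_bp: int = 1_000_000
    ne_snps: int = 1000
    max_ld_regions: int | None = None  # cap on per-region LD analyses
    out_dir: str | None = None


@dataclass
class PipelineResult:
    dataset: GenotypeDataset
    qc_counts: dict[str, int]
    mean_fst: float
    weighted_mean_fst: float
    threshold: float
    windows: list
    regions: list
    outliers: "object"
    pca: "object"
    nj_newick: str
    admixture_cv: dict[int, float]
    best_k: int
    inbreeding: dict[str, dict[str, float]]
    f_roh: dict[str, dict[str, float]]
    ne: dict[str, float]
    region_blocks: list[list]
    report: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage; optionally write tabular outputs to ``cfg.out_dir``."""
    if cfg.input_prefix is not None:
        ds = read_ped_map(cfg.input_prefix + ".ped", cfg.input_prefix + ".map")
    else:
        sim = cfg.simulation or SimulationConfig()
        sim.seed = cfg.seed
        ds, _truth = simulate_dataset(sim)
    logger.info("loaded %d samples x %d SNPs", ds.n_samples, ds.n_snps)

    ds_qc, qc_counts = apply_filters(ds, cfg.qc)
    logger.info("QC retained %d SNPs: %s", ds_qc.n_snps, qc_counts)
    pops = ds_qc.population_labels
    if len(pops) != 2:
        raise ValueError(f"pipeline requires exactly two populations, got {pops}")
    pops = (pops[0], pops[1])

    # --- FST scan
    loci = per_locus_fst(ds_qc, pops)
    mean_fst, wmean_fst = summary_fst(loci)
    windows = sliding_window_scan(loci, ds_qc.snps, window_size=cfg.window_size)
    threshold = empirical_threshold(windows, cfg.quantile)
    candidates = [w for w in windows if w.mean_fst > threshold]
    regions = build_regions(candidates, extension_bp=cfg.extension_bp)

    # --- Bayesian verification
    bayes_cfg = cfg.bayes or BayesModelConfig()
    bayes_cfg.seed = cfg.seed + 1
    chain = rjmcmc_run(ds_qc, pops, bayes_cfg)
    outliers = posterior_outliers(chain, cfg.bayes_alpha_level)

    # --- structure
    pca_res = pca(ds_qc, cfg.n_pca_components)
    dm = ibs_distance(ds_qc)
    tree = nj_tree(dm, ds_qc.samples)
    cv, best_k = admixture_cv(
        ds_qc, range(cfg.k_range[0], cfg.k_range[1] + 1),
        folds=cfg.cv_folds, seed=cfg.seed + 2,
    )

    # --- inbreeding / Ne per population
    inb: dict[str, dict[str, float]] = {}
    froh: dict[str, dict[str, float]] = {}
    ne: dict[str, float] = {}
    for pop in pops:
        sub = ds_qc.restrict_to_population(pop)
        rep = inbreeding_coefficients(sub)
        segs = detect_roh(
            sub, min_snps=cfg.roh_min_snps, min_length_bp=cfg.roh_min_length_bp
        )
        fr = f_roh(segs, sub)
        inb[pop] = {
            "f_grm": float(np.nanmean(rep.f_grm)),
            "f_mom": float(np.nanmean(rep.f_mom)),
            "f_u": float(np.nanmean(rep.f_u)),
        }
        froh[pop] = fr
        try:
            ne[pop] = ne_ld(sub, n_snps_sampled=cfg.ne_snps, seed=cfg.seed + 3).ne
        except ValueError:
            ne[pop] = float("nan")

    # --- region-local haplotype blocks
    region_blocks: list[list] = []
    chroms = ds_qc.chromosomes()
    pos = ds_qc.positions()
    ld_regions = regions if cfg.max_ld_regions is None else regions[: cfg.max_ld_regions]
    for reg in ld_regions:
        sel = np.flatnonzero(
            (chroms == reg.chromosome)
            & (pos >= reg.start_bp)
            & (pos <= reg.end_bp)
        )
        if sel.size < 2:
            region_blocks.append([])
            continue
        pairs = pairwise_ld(ds_qc, sel)
        region_blocks.append(gabriel_blocks(pairs, ds_qc, sel))

    report = consolidate_report(ds_qc, regions, outliers, region_blocks,
                                alpha_level=cfg.bayes_alpha_level)

    result = PipelineResult(
        dataset=ds_qc,
        qc_counts=qc_counts,
        mean_fst=mean_fst,
        weighted_mean_fst=wmean_fst,
        threshold=threshold,
        windows=windows,
        regions=regions,
        outliers=outliers,
        pca=pca_res,
        nj_newick=tree.newick,
        admixture_cv=cv,
        best_k=best_k,
        inbreeding=inb,
        f_roh=froh,
        ne=ne,
        region_blocks=region_blocks,
        report=report,
    )
    if cfg.out_dir is not None:
        _write_outputs(cfg, result)
    return result


def consolidate_report(
    ds: GenotypeDataset,
    regions: list,
    outliers,
    region_blocks: list[list] | None = None,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Per-region cross-reference of the window scan and the Bayesian test.

    One row per region: the fraction of contained SNPs that are Bayesian-
    significant with positive alpha (q <= alpha level), and the block count
    when region-local LD results are supplied.
    """
    chroms = ds.chromosomes()
    pos = ds.positions()
    q = outliers.q_value
    alpha = outliers.alpha_mean
    rows = []
    for r_i, reg in enumerate(regions):
        inside = np.flatnonzero(
            (chroms == reg.chromosome) & (pos >= reg.start_bp) & (pos <= reg.end_bp)
        )
        sig = (q[inside] <= alpha_level) & (alpha[inside] > 0)
        rows.append(
            {
                "chromosome": reg.chromosome,
                "start_bp": reg.start_bp,
                "end_bp": reg.end_bp,
                "size_bp": reg.size_bp,
                "peak_window_fst": reg.peak_window_fst,
                "n_snps": int(inside.size),
                "n_bayes_significant": int(sig.sum()),
                "frac_bayes_significant": float(sig.mean()) if inside.size else 0.0,
                "n_blocks": (
                    len(region_blocks[r_i])
                    if region_blocks is not None and r_i < len(region_blocks)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(cfg: PipelineConfig, res: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = res.dataset
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in ds.snps],
            "chromosome": [s.chromosome for s in ds.snps],
            "position_bp": [s.position_bp for s in ds.snps],
            "q_value": res.outliers.q_value,
            "alpha_mean": res.outliers.alpha_mean,
            "inclusion_prob": res.outliers.posterior_inclusion_prob,
            "decision": res.outliers.decision,
        }
    ).to_csv(out / "bayes_outliers.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in res.windows],
            "center_bp": [w.center_bp for w in res.windows],
            "mean_fst": [w.mean_fst for w in res.windows],
        }
    ).to_csv(out / "window_fst.tsv", sep="\t", index=False)
    res.report.to_csv(out / "regions.tsv", sep="\t", index=False)
    # regions additionally in BED (0-based half-open)
    with open(out / "regions.bed", "w") as fh:
        for r in res.regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\n")
    coords = pd.DataFrame(res.pca.coordinates)
    coords.insert(0, "sample", res.pca.samples)
    coords.to_csv(out / "pca.tsv", sep="\t", index=False)
    (out / "nj_tree.nwk").write_text(res.nj_newick + "\n")
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "n_samples": ds.n_samples,
        "n_snps_after_qc": ds.n_snps,
        "qc_counts": res.qc_counts,
        "mean_fst": res.mean_fst,
        "weighted_mean_fst": res.weighted_mean_fst,
        "window_threshold": res.threshold,
        "n_regions": len(res.regions),
        "admixture_cv": res.admixture_cv,
        "best_k": res.best_k,
        "inbreeding": res.inbreeding,
        "f_roh_mean": {
            pop: float(np.mean(list(v.values()))) for pop, v in res.f_roh.items()
        },
        "ne": res.ne,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
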
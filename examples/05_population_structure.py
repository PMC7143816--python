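"""Population structure: PCA, 1-IBS distances, NJ cladogram, admixture.

Two simulated breeds at FST 0.05 separate on PC1; the 1-IBS neighbor-joining
cladogram groups animals by breed; admixture cross-validation selects K=2.
"""

import numpy as np

from divscan import (
    SimulationConfig, admixture_cv, admixture_fit, ibs_distance, nj_tree,
    pca, simulate_dataset,
)

cfg = SimulationConfig(
    seed=11, n_snps=800, n_pop1=50, n_pop2=40, background_fst=0.05,
    n_outlier_loci=8, outlier_fst=0.3, founder_haplotypes=200,
    missing_rate=0.01, roh_per_individual=0,
)
ds, _ = simulate_dataset(cfg)
lab = np.asarray(ds.populations)

res = pca(ds, n_components=4)
print("PC1 explains "
      f"{100 * res.explained_variance_fraction[0]:.1f}% of variance; "
      f"SOK PC1 range [{res.coordinates[lab == 'SOK', 0].min():.1f}, "
      f"{res.coordinates[lab == 'SOK', 0].max():.1f}], SZTUM "
      f"[{res.coordinates[lab == 'SZTUM', 0].min():.1f}, "
      f"{res.coordinates[lab == 'SZTUM', 0].max():.1f}]")

dm = ibs_distance(ds)
print(f"mean 1-IBS distance within SOK "
      f"{dm[np.ix_(lab == 'SOK', lab == 'SOK')].mean():.3f}, "
      f"between breeds "
      f"{dm[np.ix_(lab == 'SOK', lab == 'SZTUM')].mean():.3f}")

tree = nj_tree(dm, ds.samples)
print(f"NJ cladogram with {ds.n_samples} leaves (Newick, first 60 chars): "
      f"{tree.newick[:60]}...")

cv, best = admixture_cv(ds, range(1, 6), folds=3, seed=0, max_iter=300)
print("admixture CV error by K:",
      {k: round(v, 4) for k, v in cv.items()}, f"-> best K = {best}")
fit = admixture_fit(ds, best, seed=1, max_iter=400)
print(f"mean max membership coefficient at K={best}: "
      f"{fit.Q.max(axis=1).mean():.3f}")
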
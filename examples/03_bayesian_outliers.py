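"""Bayesian verification of selection signals (FST decomposition).

Locus-population FST is decomposed on the logistic scale into a locus
effect (alpha) and a population effect (beta) under a beta-binomial model;
a reversible-jump MCMC mixes over inclusion of alpha per locus.  Loci with
low q-value and positive alpha are called as under diversifying selection.
Run time: a couple of minutes at these scaled-down settings.
"""

import numpy as np

from divscan import (
    BayesModelConfig, SimulationConfig, posterior_outliers, rjmcmc_run,
    simulate_dataset,
)

cfg = SimulationConfig(
    seed=3, n_snps=1000, n_pop1=60, n_pop2=60, n_outlier_loci=12,
    outlier_fst=0.3, founder_haplotypes=400, missing_rate=0.0,
    roh_per_individual=0, outlier_cluster_size=1,
)
ds, truth = simulate_dataset(cfg)

chain = rjmcmc_run(ds, cfg=BayesModelConfig(
    n_iterations=5000, burn_in=1000, pilot_runs=3, seed=7))
post = posterior_outliers(chain, alpha_level=0.05)

is_out = np.zeros(cfg.n_snps, bool)
is_out[truth.outlier_indices] = True
print(f"population effects beta: {np.round(chain.beta_mean, 2)} "
      f"(logit scale; sigmoid(beta) is the background FST, "
      f"{1/(1+np.exp(-chain.beta_mean.mean())):.4f})")
print(f"median inclusion probability: outliers "
      f"{np.median(post.posterior_inclusion_prob[is_out]):.2f}, "
      f"background {np.median(post.posterior_inclusion_prob[~is_out]):.2f}")
sig = post.q_value <= 0.05
print(f"{sig.sum()} loci at q<=0.05, of which {int((sig & is_out).sum())} "
      f"are planted outliers; all have positive alpha: "
      f"{bool(np.all(post.alpha_mean[sig] > 0))}")
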
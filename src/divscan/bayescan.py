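"""Bayesian FST-decomposition outlier test (reversible-jump MCMC).

Locus-population differentiation is modelled by decomposing FST on the
logistic scale into a locus-specific selection effect and a shared
population effect:

    logit(fst_ij) = alpha_i + beta_j

Allele counts at locus i in population j follow a beta-binomial
(the biallelic specialisation of the multinomial-Dirichlet model):

    k_ij ~ BetaBinomial(n_ij, theta_ij * p_i, theta_ij * (1 - p_i)),
    theta_ij = 1/fst_ij - 1 = exp(-(alpha_i + beta_j))

where p_i is the ancestral allele frequency.  A reversible-jump move
toggles the presence of alpha_i, so each locus mixes over a neutral model
(alpha absent) and a selection model; the posterior inclusion probability
of alpha_i, together with its sign, classifies loci as under diversifying
(alpha > 0) or balancing/purifying (alpha < 0) selection.  The prior odds
for the neutral model default to 10:1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, gammaln, logit

from .io import MISSING, GenotypeDataset

__all__ = [
    "BayesModelConfig",
    "RjChain",
    "OutlierPosterior",
    "locus_loglikelihood",
    "rjmcmc_run",
    "posterior_outliers",
]

_PILOT_LENGTH = 500
_ACC_LOW, _ACC_HIGH = 0.25, 0.45
_ALPHA_PRIOR_SD = 3.0
_BETA_PRIOR_MEAN, _BETA_PRIOR_SD = -1.0, 1.8


@dataclass
class BayesModelConfig:
    """MCMC controls; defaults mirror the cited outlier-test tool's."""

    prior_odds_neutral: float = 10.0
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    pilot_runs: int = 5
    proposal_sd_alpha: float = 1.0
    proposal_sd_beta: float = 0.25
    proposal_sd_freq: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.prior_odds_neutral <= 0:
            raise ValueError("prior_odds_neutral must be > 0")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must be < n_iterations")
        if min(
            self.proposal_sd_alpha, self.proposal_sd_beta, self.proposal_sd_freq
        ) <= 0:
            raise ValueError("proposal sds must be positive")


@dataclass
class RjChain:
    """Posterior summaries accumulated over the kept iterations."""

    snp_ids: list[str]
    pops: tuple[str, str]
    pip: np.ndarray  # posterior inclusion probability per locus
    alpha_mean: np.ndarray  # mean alpha over iterations where included (0 if never)
    beta_mean: np.ndarray  # (2,)
    beta_samples: np.ndarray  # thinned (n_kept, 2) for diagnostics
    n_kept: int
    geweke_z: np.ndarray  # (2,)


@dataclass
class OutlierPosterior:
    snp_ids: list[str]
    posterior_inclusion_prob: np.ndarray
    alpha_mean: np.ndarray
    q_value: np.ndarray
    beta_mean: np.ndarray
    decision: list[str]  # diversifying | balancing/purifying | neutral


def _bb_loglik(
    k: np.ndarray, n: np.ndarray, log_cnk: np.ndarray, p: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Elementwise log beta-binomial mass, parameters (theta*p, theta*(1-p))."""
    a = theta * p
    b = theta * (1.0 - p)
    return log_cnk + betaln(k + a, n - k + b) - betaln(a, b)


def locus_loglikelihood(
    k: np.ndarray | list[float],
    n: np.ndarray | list[float],
    p: float,
    fst: np.ndarray | list[float],
) -> float:
    """Log-likelihood of one locus's per-population allele counts.

    ``k``/``n`` are counted-allele counts and allele totals per population;
    ``fst`` the per-population locus FST values in (0,1).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    fst = np.asarray(fst, dtype=float)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0,1)")
    if np.any((fst <= 0.0) | (fst >= 1.0)):
        raise ValueError("fst values must lie in (0,1)")
    theta = 1.0 / fst - 1.0
    log_cnk = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(_bb_loglik(k, n, log_cnk, p, theta).sum())


def _allele_counts(
    ds: GenotypeDataset, pops: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Counted-allele counts k and allele totals n, shape (L, 2)."""
    k = np.empty((ds.n_snps, 2))
    n = np.empty((ds.n_snps, 2))
    for j, pop in enumerate(pops):
        d = ds.dosages[ds.population_mask(pop)]
        obs = d != MISSING
        k[:, j] = np.where(obs, d, 0).sum(axis=0)
        n[:, j] = 2.0 * obs.sum(axis=0)
    return k, n


def rjmcmc_run(
    ds: GenotypeDataset,
    pops: tuple[str, str] | None = None,
    cfg: BayesModelConfig | None = None,
) -> RjChain:
    """Run the reversible-jump sampler; deterministic given ``cfg.seed``.

    Update sweep per iteration: logit-random-walk on each ancestral
    frequency p_i, random walk on included alpha_i, random walk on each
    beta_j, then a reversible-jump toggle of every locus's alpha inclusion
    using the alpha prior as birth proposal.  Pilot runs adapt the three
    proposal sds toward an acceptance rate in [0.25, 0.45].
    """
    cfg = cfg or BayesModelConfig()
    cfg.validate()
    labels = ds.population_labels
    if pops is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two populations, found {labels}")
        pops = (labels[0], labels[1])
    rng = np.random.default_rng(cfg.seed)

    k, n = _allele_counts(ds, pops)
    if np.any(n < 1):
        raise ValueError("every locus needs >= 1 allele observed per population")
    L = ds.n_snps
    log_cnk = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    pi_incl = 1.0 / (1.0 + cfg.prior_odds_neutral)
    log_prior_odds_incl = np.log(pi_incl) - np.log1p(-pi_incl)

    # initial state
    p = (k.sum(axis=1) + 1.0) / (n.sum(axis=1) + 2.0)
    beta = np.full(2, _BETA_PRIOR_MEAN)
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    sd_p = cfg.proposal_sd_freq
    sd_a = cfg.proposal_sd_alpha
    sd_b = cfg.proposal_sd_beta

    def loglik_matrix(p_, alpha_, delta_, beta_) -> np.ndarray:
        theta = np.exp(-((alpha_ * delta_)[:, None] + beta_[None, :]))
        return _bb_loglik(k, n, log_cnk, p_[:, None], theta)

    ll = loglik_matrix(p, alpha, delta, beta)  # (L, 2)

    n_kept = 0
    pip_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    alpha_cnt = np.zeros(L)
    beta_sum = np.zeros(2)
    beta_store: list[np.ndarray] = []

    def sweep(adapt_counters: dict[str, list[float]] | None) -> None:
        nonlocal p, beta, alpha, delta, ll
        # --- ancestral frequencies on logit scale (uniform prior on p)
        x = logit(p)
        x_new = x + rng.normal(0.0, sd_p, size=L)
        p_new = expit(x_new)
        ll_new = loglik_matrix(p_new, alpha, delta, beta)
        # Jacobian of logit transform: prior density on x is p(1-p)
        log_acc = (
            ll_new.sum(axis=1)
            - ll.sum(axis=1)
            + np.log(p_new * (1 - p_new))
            - np.log(p * (1 - p))
        )
        acc = np.log(rng.random(L)) < log_acc
        p = np.where(acc, p_new, p)
        ll[acc] = ll_new[acc]
        if adapt_counters is not None:
            adapt_counters["p"].append(acc.mean())

        # --- alpha random walk (included loci only)
        a_new = alpha + rng.normal(0.0, sd_a, size=L)
        ll_new = loglik_matrix(p, a_new, delta, beta)
        log_acc = (
            ll_new.sum(axis=1)
            - ll.sum(axis=1)
            + (alpha**2 - a_new**2) / (2.0 * _ALPHA_PRIOR_SD**2)
        )
        acc = delta & (np.log(rng.random(L)) < log_acc)
        alpha = np.where(acc, a_new, alpha)
        ll[acc] = ll_new[acc]
        if adapt_counters is not None and delta.any():
            adapt_counters["alpha"].append(acc[delta].mean())

        # --- beta random walks (one column at a time)
        for j in range(2):
            b_new = beta.copy()
            b_new[j] += rng.normal(0.0, sd_b)
            theta_j = np.exp(-((alpha * delta) + b_new[j]))
            ll_col = _bb_loglik(k[:, j], n[:, j], log_cnk[:, j], p, theta_j)
            log_acc = (
                ll_col.sum()
                - ll[:, j].sum()
                + ((beta[j] - _BETA_PRIOR_MEAN) ** 2 - (b_new[j] - _BETA_PRIOR_MEAN) ** 2)
                / (2.0 * _BETA_PRIOR_SD**2)
            )
            if np.log(rng.random()) < log_acc:
                beta = b_new
                ll[:, j] = ll_col
                if adapt_counters is not None:
                    adapt_counters["beta"].append(1.0)
            elif adapt_counters is not None:
                adapt_counters["beta"].append(0.0)

        # --- reversible jump: toggle inclusion, prior as birth proposal
        a_birth = rng.normal(0.0, _ALPHA_PRIOR_SD, size=L)
        d_prop = ~delta
        ll_new = loglik_matrix(p, np.where(delta, alpha, a_birth), d_prop, beta)
        # prior density of alpha cancels against the birth proposal density
        log_acc = (
            ll_new.sum(axis=1)
            - ll.sum(axis=1)
            + np.where(delta, -log_prior_odds_incl, log_prior_odds_incl)
        )
        acc = np.log(rng.random(L)) < log_acc
        alpha = np.where(acc, np.where(delta, 0.0, a_birth), alpha)
        delta = np.where(acc, d_prop, delta)
        ll[acc] = ll_new[acc]

    # pilot adaptation
    for _ in range(cfg.pilot_runs):
        counters: dict[str, list[float]] = {"p": [], "alpha": [], "beta": []}
        for _ in range(_PILOT_LENGTH):
            sweep(counters)
        for key, rates in counters.items():
            if not rates:
                continue
            rate = float(np.mean(rates))
            factor = 1.0
            if rate > _ACC_HIGH:
                factor = 1.3
            elif rate < _ACC_LOW:
                factor = 1.0 / 1.3
            if key == "p":
                sd_p *= factor
            elif key == "alpha":
                sd_a *= factor
            else:
                sd_b *= factor

    for it in range(cfg.n_iterations):
        sweep(None)
        if it >= cfg.burn_in:
            n_kept += 1
            pip_sum += delta
            alpha_sum += np.where(delta, alpha, 0.0)
            alpha_cnt += delta
            beta_sum += beta
            if (it - cfg.burn_in) % cfg.thinning == 0:
                beta_store.append(beta.copy())

    beta_samples = np.asarray(beta_store)
    geweke = _geweke_z(beta_samples)
    if np.any(np.abs(geweke) > 3.0):
        warnings.warn(
            f"possible non-convergence: Geweke z on beta = {geweke}", RuntimeWarning
        )
    with np.errstate(invalid="ignore"):
        alpha_mean = np.where(alpha_cnt > 0, alpha_sum / np.maximum(alpha_cnt, 1), 0.0)
    return RjChain(
        snp_ids=[s.snp_id for s in ds.snps],
        pops=pops,
        pip=pip_sum / n_kept,
        alpha_mean=alpha_mean,
        beta_mean=beta_sum / n_kept,
        beta_samples=beta_samples,
        n_kept=n_kept,
        geweke_z=geweke,
    )


def _geweke_z(samples: np.ndarray) -> np.ndarray:
    """Geweke convergence z-score (first 10% vs last 50%) per column."""
    if samples.ndim != 2 or samples.shape[0] < 20:
        return np.zeros(samples.shape[-1] if samples.ndim == 2 else 2)
    m = samples.shape[0]
    first = samples[: max(2, m // 10)]
    last = samples[m // 2 :]
    var = first.var(axis=0, ddof=1) / len(first) + last.var(axis=0, ddof=1) / len(last)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (first.mean(axis=0) - last.mean(axis=0)) / np.sqrt(var)
    return np.where(np.isfinite(z), z, 0.0)


def posterior_outliers(chain: RjChain, alpha_level: float = 0.05) -> OutlierPosterior:
    """Per-locus q-values and selection decisions from a sampled chain.

    The q-value of a locus is the mean posterior error rate (1 - inclusion
    probability) among all loci with inclusion probability at least as
    large.  A locus is called diversifying when q <= ``alpha_level`` and its
    posterior mean alpha is positive, balancing/purifying when negative.
    """
    if chain.n_kept < 1:
        raise ValueError("chain has no kept iterations")
    pip = chain.pip
    order = np.argsort(-pip, kind="stable")
    per = 1.0 - pip[order]
    q_sorted = np.cumsum(per) / np.arange(1, len(per) + 1)
    # enforce monotonicity in the sorted order (cumulative means already are
    # monotone when pip is sorted, up to ties; make it explicit)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    decision = []
    for qi, am in zip(q, chain.alpha_mean):
        if qi <= alpha_level and am > 0:
            decision.append("diversifying")
        elif qi <= alpha_level and am < 0:
            decision.append("balancing/purifying")
        else:
            decision.append("neutral")
    return OutlierPosterior(
        snp_ids=list(chain.snp_ids),
        posterior_inclusion_prob=pip.copy(),
        alpha_mean=chain.alpha_mean.copy(),
        q_value=q,
        beta_mean=chain.beta_mean.copy(),
        decision=decision,
    )
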
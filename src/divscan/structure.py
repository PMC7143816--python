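"""Population structure: PCA, 1-IBS distances, NJ cladogram and admixture.

PCA uses the usual genotype standardisation (centre by 2p, scale by
sqrt(2p(1-p))) with mean imputation at missing cells.  The inter-individual
distance is 1 - IBS, with IBS the probability that two alleles drawn at
random, one from each individual at the same locus, are identical-by-state.
Neighbor-joining on that distance matrix is delegated to scikit-bio.
Admixture proportions maximise the binomial genotype likelihood over Q
(individual membership coefficients) and P (cluster allele frequencies) by
EM; the best number of clusters K is chosen by masked-cell cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .io import MISSING, GenotypeDataset

__all__ = [
    "PcaResult",
    "NjTree",
    "AdmixtureFit",
    "pca",
    "ibs_distance",
    "nj_tree",
    "admixture_fit",
    "admixture_cv",
]

_P_EPS = 1e-6


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    explained_variance_fraction: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class NjTree:
    tree: "object"  # skbio.TreeNode
    newick: str


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_samples, K), rows sum to 1
    P: np.ndarray  # (K, n_snps) counted-allele frequencies
    loglikelihood: float
    loglik_trace: np.ndarray
    cv_error: float = float("nan")


def pca(ds: GenotypeDataset, n_components: int = 10) -> PcaResult:
    """Genotype PCA with allele-frequency standardisation.

    Missing cells are mean-imputed; each SNP column is centred by 2p and
    scaled by sqrt(2p(1-p)); monomorphic SNPs are dropped.  Coordinates are
    the projections onto the top eigenvectors of the sample covariance, so
    the variance of PC k equals the k-th eigenvalue.
    """
    if ds.n_samples < 2 or ds.n_snps < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 SNPs")
    d = ds.dosages.astype(float)
    obs = ds.dosages != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    keep = (n_obs > 0) & (p > 0) & (p < 1)
    d = d[:, keep]
    p = p[keep]
    obsk = obs[:, keep]
    d = np.where(obsk, d, 2.0 * p)
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z -= z.mean(axis=0)  # imputation keeps column means at 2p exactly anyway
    max_comp = min(ds.n_samples - 1, z.shape[1])
    n_components = min(n_components, max_comp)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (ds.n_samples - 1)
    total_var = (z**2).sum() / (ds.n_samples - 1)
    coords = u[:, :n_components] * s[:n_components]
    return PcaResult(
        samples=list(ds.samples),
        coordinates=coords,
        explained_variance_fraction=eigvals[:n_components] / total_var,
        eigenvalues=eigvals[:n_components],
    )


def ibs_distance(ds: GenotypeDataset) -> np.ndarray:
    """Symmetric (n_samples, n_samples) matrix of 1 - IBS similarity.

    Per locus, IBS between dosages d_i and d_j is 1 - |d_i - d_j|/2; the
    pairwise similarity averages over loci genotyped in both individuals.
    Raises ``ValueError`` for a pair with no jointly genotyped locus.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = ds.dosages.astype(float)
    obs = (ds.dosages != MISSING).astype(float)
    d0 = np.where(obs > 0, d, 0.0)
    # sum over loci of |d_i - d_j| restricted to joint observation:
    # |d_i - d_j| expands over the 3 dosage levels; use one-hot encoding
    levels = [(ds.dosages == lv).astype(float) for lv in (0, 1, 2)]
    joint = obs @ obs.T
    absdiff = np.zeros_like(joint)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (levels[a] @ levels[b].T)
    if np.any(joint[~np.eye(ds.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((joint == 0) & ~np.eye(ds.n_samples, dtype=bool))[0]
        raise ValueError(
            f"samples {ds.samples[i]} and {ds.samples[j]} share no genotyped locus"
        )
    dist = absdiff / (2.0 * joint)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def nj_tree(dm: np.ndarray, ids: list[str]) -> NjTree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Negative branch lengths are clamped to zero.  Returns the tree and its
    Newick serialisation.
    """
    dm = np.asarray(dm, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if dm.shape[0] < 3:
        raise ValueError("NJ needs >= 3 taxa")
    tree = _skbio_nj(DistanceMatrix(dm, ids), neg_as_zero=True)
    return NjTree(tree=tree, newick=str(tree).strip())


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------

def _admixture_loglik(d, obs, Q, P) -> float:
    mu = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
    ll = np.where(obs, d * np.log(mu) + (2.0 - d) * np.log(1.0 - mu), 0.0)
    return float(ll.sum())


def admixture_fit(
    ds: GenotypeDataset,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-4,
    _masked: np.ndarray | None = None,
) -> AdmixtureFit:
    """Maximum-likelihood admixture proportions for K ancestral clusters.

    EM block updates of Q (membership) and P (cluster allele frequencies)
    on the binomial genotype likelihood, iterated until the log-likelihood
    gain is < ``tol`` or ``max_iter`` sweeps.  Missing cells (and any cells
    in the optional ``_masked`` boolean matrix, used by cross-validation)
    are skipped.  Initialisation: Q rows ~ Dirichlet(1,...,1), P jittered
    around the overall allele frequencies, from ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_samples:
        raise ValueError("K exceeds the number of samples")
    rng = np.random.default_rng(seed)
    d = ds.dosages.astype(float)
    obs = ds.dosages != MISSING
    if _masked is not None:
        obs = obs & ~_masked
    d = np.where(obs, d, 0.0)
    n, L = d.shape
    freq = d.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)

    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(
        freq[None, :] + rng.normal(0.0, 0.1, size=(K, L)), _P_EPS, 1 - _P_EPS
    )
    if K == 1:
        Q = np.ones((n, 1))
        P = np.clip(freq[None, :], _P_EPS, 1 - _P_EPS)

    trace = [_admixture_loglik(d, obs, Q, P)]
    for _ in range(max_iter):
        mu = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
        # responsibilities for the "1" and "0" allele copies at each cell
        ra = d / mu  # (n, L)
        rb = (2.0 - d) / (1.0 - mu)
        ra = np.where(obs, ra, 0.0)
        rb = np.where(obs, rb, 0.0)
        A = (ra @ P.T) * Q  # expected counted-allele copies from cluster k
        B = (rb @ (1.0 - P).T) * Q
        Q_new = A + B
        Q_new /= np.maximum(Q_new.sum(axis=1, keepdims=True), 1e-300)
        Ak = (Q.T @ ra) * P  # per cluster/locus expected counted copies
        Bk = (Q.T @ rb) * (1.0 - P)
        P_new = np.clip(Ak / np.maximum(Ak + Bk, 1e-300), _P_EPS, 1 - _P_EPS)
        Q, P = Q_new, P_new
        trace.append(_admixture_loglik(d, obs, Q, P))
        if trace[-1] - trace[-2] < tol:
            break
    return AdmixtureFit(
        K=K, Q=Q, P=P, loglikelihood=trace[-1], loglik_trace=np.asarray(trace)
    )


def admixture_cv(
    ds: GenotypeDataset,
    K_range: range | list[int] = range(1, 6),
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> tuple[dict[int, float], int]:
    """Cross-validated choice of K.

    The non-missing genotype cells are split at random into ``folds``
    groups; for each fold the fit is run with that group masked and the
    error is the mean squared deviation between held-out dosages and their
    fitted expectations 2 * sum_k q_ik p_kl.  Returns the per-K mean error
    and the argmin K.
    """
    K_list = list(K_range)
    if not K_list:
        raise ValueError("empty K range")
    rng = np.random.default_rng(seed)
    obs = ds.dosages != MISSING
    fold_id = np.full(ds.dosages.shape, -1, dtype=np.int8)
    cells = np.argwhere(obs)
    perm = rng.permutation(len(cells))
    for f in range(folds):
        sel = cells[perm[f::folds]]
        fold_id[sel[:, 0], sel[:, 1]] = f

    d = ds.dosages.astype(float)
    cv: dict[int, float] = {}
    for K in K_list:
        errs = []
        for f in range(folds):
            mask = fold_id == f
            fit = admixture_fit(
                ds, K, seed=int(rng.integers(2**31 - 1)), max_iter=max_iter,
                _masked=mask,
            )
            mu = 2.0 * (fit.Q @ fit.P)
            held = mask & obs
            errs.append(float(((d - mu)[held] ** 2).mean()))
        cv[K] = float(np.mean(errs))
    best = min(cv, key=cv.get)
    return cv, best
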
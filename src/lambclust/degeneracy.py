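"""Numerical lab for the high-dimensional degeneracy of Gaussian mixture posteriors.

Implements, exactly and in log space:

* marginal likelihoods of multivariate-Gaussian clusters under conjugate
  normal-inverse-Wishart priors, both with cluster-specific covariances and
  with a covariance shared across clusters;
* the Dirichlet-process exchangeable partition probability function (EPPF);
* exhaustive partition posteriors over all set partitions of small samples;
* the merge-ratio statistic whose limiting behavior (0 or infinity as the
  dimension p grows) drives the posterior to all-one-cluster or
  all-singletons regardless of the true structure in the data;
* the Bayes-oracle partition posterior computed on the true latent factors
  under a location mixture with shared covariance and Jeffreys prior.

Determinants of diagonal-plus-low-rank p x p matrices are evaluated through
the matrix determinant lemma on the n x n Gram matrix, so p in the thousands
costs the same as p = 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp, multigammaln

__all__ = [
    "GaussianNIWPrior",
    "Partition",
    "set_partitions",
    "log_marginal_niw",
    "log_marginal_niw_cluster",
    "log_marginal_shared_cov",
    "dp_eppf_logprior",
    "exhaustive_partition_posterior",
    "merge_ratio_statistic",
    "oracle_log_marginal",
    "oracle_partition_posterior",
]


@dataclass(frozen=True)
class GaussianNIWPrior:
    """NIW prior (mu0, kappa0, nu0, Lambda0) for p-variate Gaussian clusters.

    ``Lambda0`` may be a dense SPD matrix, a length-p vector (diagonal), or a
    scalar s meaning s * I_p.  ``shared_covariance`` selects the common-Sigma
    regime in which all clusters share one covariance drawn from
    IW(nu0, Lambda0).
    """

    mu0: np.ndarray | float
    kappa0: float
    nu0: float
    Lambda0: np.ndarray | float
    shared_covariance: bool = False

    def __post_init__(self) -> None:
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")

    def lambda0_diag(self, p: int) -> np.ndarray | None:
        """Diagonal of Lambda0 when it has a diagonal representation, else None."""
        L0 = self.Lambda0
        if np.isscalar(L0):
            return np.full(p, float(L0))
        L0 = np.asarray(L0, dtype=float)
        if L0.ndim == 1:
            return L0
        return None

    def lambda0_dense(self, p: int) -> np.ndarray:
        diag = self.lambda0_diag(p)
        if diag is not None:
            return np.diag(diag)
        return np.asarray(self.Lambda0, dtype=float)

    def mu0_vector(self, p: int) -> np.ndarray:
        if np.isscalar(self.mu0):
            return np.full(p, float(self.mu0))
        return np.asarray(self.mu0, dtype=float)


@dataclass(frozen=True)
class Partition:
    """A set partition of {0, ..., n-1} stored as sorted tuples of blocks."""

    blocks: tuple[tuple[int, ...], ...]

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        labels = np.asarray(labels)
        blocks = []
        for lab in dict.fromkeys(labels.tolist()):
            blocks.append(tuple(int(i) for i in np.where(labels == lab)[0]))
        return cls(tuple(sorted(blocks)))

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    def labels(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=int)
        for h, block in enumerate(self.blocks):
            for i in block:
                out[i] = h
        return out


def set_partitions(n: int) -> Iterator[np.ndarray]:
    """Yield every set partition of {0..n-1} as a restricted-growth label vector."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    while True:
        yield labels.copy()
        # next restricted-growth string
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]


# ---------------------------------------------------------------------------
# marginal likelihoods
# ---------------------------------------------------------------------------


def _logdet_lambda_n(Yc: np.ndarray, prior: GaussianNIWPrior, weights: np.ndarray) -> float:
    """log |Lambda0 + Yc^T W Yc| for a symmetric n x n weight matrix W.

    Uses the Gram/capacitance identity |Lambda0 + Yc^T W Yc| =
    |Lambda0| |I_n + W Yc Lambda0^{-1} Yc^T| when Lambda0 is diagonal and
    n < p; dense otherwise.
    """
    n, p = Yc.shape
    diag = prior.lambda0_diag(p)
    if diag is not None and n < p:
        G = (Yc / diag[None, :]) @ Yc.T
        sign, ld = np.linalg.slogdet(np.eye(n) + weights @ G)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior scale matrix is not positive definite")
        return float(np.sum(np.log(diag)) + ld)
    L0 = prior.lambda0_dense(p)
    M = L0 + Yc.T @ (weights @ Yc)
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior scale matrix is not positive definite")
    return float(ld)


def _logdet_lambda0(prior: GaussianNIWPrior, p: int) -> float:
    diag = prior.lambda0_diag(p)
    if diag is not None:
        return float(np.sum(np.log(diag)))
    sign, ld = np.linalg.slogdet(prior.lambda0_dense(p))
    if sign <= 0:
        raise np.linalg.LinAlgError("Lambda0 is not positive definite")
    return float(ld)


def log_marginal_niw(X: np.ndarray, kappa0: float, nu0: float, Lambda0, mu0=0.0) -> float:
    """Log marginal likelihood of an n x p Gaussian block under an NIW prior.

    Convenience wrapper over :func:`log_marginal_niw_cluster` with scalar /
    vector / matrix ``Lambda0``.
    """
    prior = GaussianNIWPrior(mu0=mu0, kappa0=kappa0, nu0=nu0, Lambda0=Lambda0)
    return log_marginal_niw_cluster(np.atleast_2d(X), prior)


def log_marginal_niw_cluster(Yh: np.ndarray, prior: GaussianNIWPrior) -> float:
    """Log integral of the Gaussian likelihood of one cluster over its NIW prior.

    For an n_h x p block: -(n_h p/2) log pi + (p/2) log{kappa0/(kappa0+n_h)}
    + log Gamma_p((nu0+n_h)/2) - log Gamma_p(nu0/2) + (nu0/2) log|Lambda0|
    - ((nu0+n_h)/2) log|Lambda_n|, with Lambda_n = Lambda0 + S_h +
    (kappa0 n_h/(kappa0+n_h)) (ybar - mu0)(ybar - mu0)^T.  Empty blocks give 0.
    """
    Yh = np.atleast_2d(np.asarray(Yh, dtype=float))
    nh, p = Yh.shape
    if nh == 0:
        return 0.0
    if prior.nu0 + nh - p + 1 <= 0 or prior.nu0 <= p - 1:
        raise ValueError("nu0 too small for this block (need nu0 > p - 1)")
    Yc = Yh - prior.mu0_vector(p)[None, :]
    kn = prior.kappa0 + nh
    # S_h + (kappa0 nh / kn) ybar ybar^T  =  Yc^T (I - J/kn) Yc
    W = np.eye(nh) - np.full((nh, nh), 1.0 / kn)
    logdet_n = _logdet_lambda_n(Yc, prior, W)
    return float(
        -0.5 * nh * p * np.log(np.pi)
        + 0.5 * p * np.log(prior.kappa0 / kn)
        + multigammaln((prior.nu0 + nh) / 2.0, p)
        - multigammaln(prior.nu0 / 2.0, p)
        + 0.5 * prior.nu0 * _logdet_lambda0(prior, p)
        - 0.5 * (prior.nu0 + nh) * logdet_n
    )


def log_marginal_shared_cov(Y: np.ndarray, partition: Partition, prior: GaussianNIWPrior) -> float:
    """Log marginal of the whole sample when all clusters share one covariance.

    Sigma ~ IW(nu0, Lambda0) common to every block; cluster means have
    independent N(mu0, Sigma/kappa0) priors and are integrated out.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if partition.n != n:
        raise ValueError("partition size does not match the data")
    if prior.nu0 <= p - 1:
        raise ValueError("nu0 must exceed p - 1")
    Yc = Y - prior.mu0_vector(p)[None, :]
    W = np.eye(n)
    log_kappa_term = 0.0
    for block in partition.blocks:
        nh = len(block)
        kn = prior.kappa0 + nh
        idx = np.array(block)
        W[np.ix_(idx, idx)] -= 1.0 / kn
        log_kappa_term += 0.5 * p * np.log(prior.kappa0 / kn)
    logdet_n = _logdet_lambda_n(Yc, prior, W)
    return float(
        -0.5 * n * p * np.log(np.pi)
        + log_kappa_term
        + multigammaln((prior.nu0 + n) / 2.0, p)
        - multigammaln(prior.nu0 / 2.0, p)
        + 0.5 * prior.nu0 * _logdet_lambda0(prior, p)
        - 0.5 * (prior.nu0 + n) * logdet_n
    )


def dp_eppf_logprior(partition: Partition, alpha: float) -> float:
    """Dirichlet-process EPPF: log[alpha^k prod_h (n_h-1)! Gamma(alpha)/Gamma(alpha+n)]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sizes = partition.sizes
    n = sum(sizes)
    k = len(sizes)
    return float(
        k * np.log(alpha)
        + sum(gammaln(nh) for nh in sizes)
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


# ---------------------------------------------------------------------------
# exhaustive posteriors
# ---------------------------------------------------------------------------


def _subset_log_marginals(Y: np.ndarray, prior: GaussianNIWPrior) -> dict[int, float]:
    """Log marginal of every non-empty subset of rows, keyed by bitmask.

    Shares the n x n Gram matrix across subsets so that the per-subset cost is
    O(n_h^3) regardless of p (diagonal Lambda0) and caches the Gamma_p terms
    per block size.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    Yc = Y - prior.mu0_vector(p)[None, :]
    diag = prior.lambda0_diag(p)
    logdet0 = _logdet_lambda0(prior, p)
    if diag is not None and n < p:
        G = (Yc / diag[None, :]) @ Yc.T
    else:
        G = None
    gamma_term = {}
    for nh in range(1, n + 1):
        gamma_term[nh] = multigammaln((prior.nu0 + nh) / 2.0, p) - multigammaln(prior.nu0 / 2.0, p)
    out: dict[int, float] = {}
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        nh = len(idx)
        kn = prior.kappa0 + nh
        W = np.eye(nh) - np.full((nh, nh), 1.0 / kn)
        if G is not None:
            sub = G[np.ix_(idx, idx)]
            sign, ld = np.linalg.slogdet(np.eye(nh) + W @ sub)
            logdet_n = float(np.sum(np.log(diag)) + ld)
        else:
            logdet_n = _logdet_lambda_n(Yc[idx], prior, W)
        out[mask] = float(
            -0.5 * nh * p * np.log(np.pi)
            + 0.5 * p * np.log(prior.kappa0 / kn)
            + gamma_term[nh]
            + 0.5 * prior.nu0 * logdet0
            - 0.5 * (prior.nu0 + nh) * logdet_n
        )
    return out


def _blocks_to_masks(labels: np.ndarray) -> list[int]:
    masks: dict[int, int] = {}
    for i, lab in enumerate(labels):
        masks[lab] = masks.get(lab, 0) | (1 << i)
    return list(masks.values())


def exhaustive_partition_posterior(
    Y: np.ndarray,
    prior: GaussianNIWPrior,
    alpha: float,
    n_max: int = 12,
) -> list[tuple[Partition, float]]:
    """Posterior probability of every set partition of the n observations.

    Combines the DP EPPF prior with the NIW marginal likelihood of each
    partition (cluster-specific or shared covariance per ``prior``),
    normalized by log-sum-exp over all Bell(n) partitions.  Refuses n > n_max.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    if n > n_max:
        raise ValueError(f"exhaustive enumeration limited to n <= {n_max} (got n={n})")
    parts: list[Partition] = []
    logpost = []
    if prior.shared_covariance:
        p = Y.shape[1]
        diag = prior.lambda0_diag(p)
        if diag is not None and n < p:
            return _exhaustive_shared_fast(Y, prior, alpha, diag)
        for labels in set_partitions(n):
            part = Partition.from_labels(labels)
            parts.append(part)
            logpost.append(dp_eppf_logprior(part, alpha) + log_marginal_shared_cov(Y, part, prior))
    else:
        cache = _subset_log_marginals(Y, prior)
        sizes_cache: dict[tuple[int, ...], float] = {}
        for labels in set_partitions(n):
            part = Partition.from_labels(labels)
            parts.append(part)
            lp = dp_eppf_logprior(part, alpha)
            lp += sum(cache[m] for m in _blocks_to_masks(labels))
            logpost.append(lp)
    logpost = np.asarray(logpost)
    probs = np.exp(logpost - logsumexp(logpost))
    return list(zip(parts, probs.tolist()))


def _exhaustive_shared_fast(
    Y: np.ndarray,
    prior: GaussianNIWPrior,
    alpha: float,
    diag: np.ndarray,
) -> list[tuple[Partition, float]]:
    """Shared-covariance exhaustive posterior via batched Gram determinants.

    log|Lambda0 + Yc^T W Yc| = sum log diag + log|I_n + W G| with the n x n
    Gram G shared across partitions; the |I + W G| determinants are evaluated
    with batched slogdet over chunks of partitions.
    """
    n, p = Y.shape
    Yc = Y - prior.mu0_vector(p)[None, :]
    G = (Yc / diag[None, :]) @ Yc.T
    base = float(
        -0.5 * n * p * np.log(np.pi)
        + multigammaln((prior.nu0 + n) / 2.0, p)
        - multigammaln(prior.nu0 / 2.0, p)
        + 0.5 * prior.nu0 * np.sum(np.log(diag))
        - 0.5 * (prior.nu0 + n) * np.sum(np.log(diag))
    )
    parts: list[Partition] = []
    prior_kappa_terms: list[float] = []
    mats: list[np.ndarray] = []
    logpost: list[float] = []
    chunk = 20000

    def flush() -> None:
        if not mats:
            return
        W = np.stack(mats)
        sign, ld = np.linalg.slogdet(np.eye(n)[None] + W @ G)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("posterior scale matrix is not positive definite")
        logpost.extend(
            (base + kt - 0.5 * (prior.nu0 + n) * l) for kt, l in zip(prior_kappa_terms, ld)
        )
        mats.clear()
        prior_kappa_terms.clear()

    for labels in set_partitions(n):
        part = Partition.from_labels(labels)
        parts.append(part)
        W = np.eye(n)
        kt = dp_eppf_logprior(part, alpha)
        for block in part.blocks:
            nh = len(block)
            kn = prior.kappa0 + nh
            idx = np.array(block)
            W[np.ix_(idx, idx)] -= 1.0 / kn
            kt += 0.5 * p * np.log(prior.kappa0 / kn)
        mats.append(W)
        prior_kappa_terms.append(kt)
        if len(mats) >= chunk:
            flush()
    flush()
    lp = np.asarray(logpost)
    probs = np.exp(lp - logsumexp(lp))
    return list(zip(parts, probs.tolist()))


def merge_ratio_statistic(
    Y: np.ndarray,
    partition: Partition,
    pair: tuple[int, int],
    prior: GaussianNIWPrior,
) -> float:
    """Log of the Theorem-1 likelihood ratio: pre-merge over post-merge.

    ``pair`` indexes the two blocks of ``partition`` to merge.  A drift of
    this statistic toward -inf as p grows forces the posterior to one
    cluster; a drift toward +inf forces all singletons.
    """
    if len(partition.blocks) < 2:
        raise ValueError("partition must have at least two blocks")
    a, b = pair
    if a == b or not (0 <= a < len(partition.blocks)) or not (0 <= b < len(partition.blocks)):
        raise ValueError("invalid pair of blocks")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    joined = tuple(sorted(partition.blocks[a] + partition.blocks[b]))
    if prior.shared_covariance:
        merged_blocks = [blk for h, blk in enumerate(partition.blocks) if h not in (a, b)]
        merged_blocks.append(joined)
        merged = Partition(tuple(sorted(merged_blocks)))
        pre = log_marginal_shared_cov(Y, partition, prior)
        post = log_marginal_shared_cov(Y, merged, prior)
        return float(pre - post)
    # cluster-specific covariances: the untouched blocks cancel in the ratio
    pre = log_marginal_niw_cluster(Y[list(partition.blocks[a])], prior) + log_marginal_niw_cluster(
        Y[list(partition.blocks[b])], prior
    )
    post = log_marginal_niw_cluster(Y[list(joined)], prior)
    return float(pre - post)


# ---------------------------------------------------------------------------
# Bayes-oracle partition posterior
# ---------------------------------------------------------------------------


def oracle_log_marginal(eta0: np.ndarray, partition: Partition, kappa0: float) -> float:
    """Log marginal of the latent factors under the oracle model, up to a constant.

    Oracle model: eta_i ~ N(mu_h, Delta) within blocks, mu_h ~ N(0, Delta/kappa0),
    Jeffreys prior Delta ∝ |Delta|^{-(d+1)/2}.  Integrating the means and
    Delta gives (dropping partition-independent constants)

        (d/2) sum_h log{kappa0/(kappa0+n_h)} - (n/2) log|S*|,

    with S* = sum_i eta_i eta_i^T - sum_h (n_h^2/(kappa0+n_h)) etabar_h etabar_h^T.
    Well defined for n > d (the improper marginal is finite there); this is
    the (nu0 -> 0, Lambda0 -> 0) limit of the shared-covariance NIW marginal.
    """
    eta0 = np.atleast_2d(np.asarray(eta0, dtype=float))
    n, d = eta0.shape
    if n <= d:
        raise ValueError("oracle rule requires n > d")
    S = eta0.T @ eta0
    log_kappa = 0.0
    for block in partition.blocks:
        nh = len(block)
        kn = kappa0 + nh
        bar = eta0[list(block)].mean(axis=0)
        S = S - (nh**2 / kn) * np.outer(bar, bar)
        log_kappa += 0.5 * d * np.log(kappa0 / kn)
    sign, ld = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("oracle scatter matrix is singular")
    return float(log_kappa - 0.5 * n * ld)


def oracle_partition_posterior(
    eta0: np.ndarray,
    kappa0: float,
    alpha: float,
    n_max: int = 12,
) -> list[tuple[Partition, float]]:
    """Bayes-oracle posterior over partitions of the true latent factors."""
    eta0 = np.atleast_2d(np.asarray(eta0, dtype=float))
    n, d = eta0.shape
    if n <= d:
        raise ValueError("oracle rule requires n > d")
    if n > n_max:
        raise ValueError(f"exhaustive enumeration limited to n <= {n_max} (got n={n})")
    parts = []
    logpost = []
    for labels in set_partitions(n):
        part = Partition.from_labels(labels)
        parts.append(part)
        logpost.append(dp_eppf_logprior(part, alpha) + oracle_log_marginal(eta0, part, kappa0))
    logpost = np.asarray(logpost)
    probs = np.exp(logpost - logsumexp(logpost))
    return list(zip(parts, probs.tolist()))
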
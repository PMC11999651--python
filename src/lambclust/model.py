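"""Latent mixture for Bayesian clustering (Lamb): model state and Gibbs sampler.

The model couples a sparse Gaussian factor measurement layer with a Dirichlet
process mixture on the low-dimensional latent factors::

    y_i ~ N_p(Lambda eta_i, Sigma),   Sigma = diag(sigma_1^2, ..., sigma_p^2)
    eta_i ~ sum_h pi_h N_d(mu_h, Delta_h)

with a Dirichlet-Laplace shrinkage prior on vec(Lambda), normal-inverse-
Wishart base measure on (mu_h, Delta_h) (mu_h always integrated out
analytically, with mu0 = 0), a gamma hyperprior on the DP concentration
alpha, and inverse-gamma priors on the residual variances.

The sampler is a collapsed Gibbs scan (loadings, cluster covariances, latent
factors, labels via the Chinese-restaurant marginal, concentration,
residual variances, shrinkage hyperparameters), optionally followed by a
Jain-Neal split-merge attempt each sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .rng import (
    GIGParams,
    sample_gig,
    sample_gig_vector,
    sample_inverse_gaussian,
    sample_inverse_wishart,
)

__all__ = [
    "DataMatrix",
    "Hyperparams",
    "DLState",
    "ModelState",
    "FitConfig",
    "FitResult",
    "update_loadings",
    "update_cluster_covariances",
    "update_latent_factors",
    "cluster_predictive_logdensity",
    "update_labels",
    "update_concentration",
    "update_residual_variances",
    "update_dl_hyperparameters",
    "gibbs_sweep",
    "fit",
    "sample_prior_state",
    "log_likelihood",
]

logger = logging.getLogger("lambclust")

_JITTER = 1e-10
_ABS_FLOOR = 1e-300  # floor on |lambda_jh| before forming iG/giG parameters


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DataMatrix:
    """Observed n x p data matrix with sample and variable names."""

    Y: np.ndarray
    row_names: Sequence[str] | None = None
    col_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-d matrix (samples x variables)")
        n, p = self.Y.shape
        if n < 2 or p < 1:
            raise ValueError("need n >= 2 samples and p >= 1 variables")
        if not np.all(np.isfinite(self.Y)):
            i, j = np.argwhere(~np.isfinite(self.Y))[0]
            raise ValueError(f"Y contains a non-finite value at row {i}, column {j}")
        if self.row_names is None:
            self.row_names = [f"row{i}" for i in range(n)]
        if self.col_names is None:
            self.col_names = [f"col{j}" for j in range(p)]
        if len(self.row_names) != n or len(self.col_names) != p:
            raise ValueError("name lengths must match matrix shape")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class Hyperparams:
    """Fixed prior constants.

    ``xi2`` scales the NIW inverse scale matrix Delta0 = xi2 * I_d; ``kappa0``
    is the NIW precision on the (marginalized) cluster means; ``nu0`` the NIW
    degrees of freedom (default d + 50); ``a_alpha``/``b_alpha`` the gamma
    prior (shape/rate) on the DP concentration; ``a_sigma``/``b_sigma`` the
    gamma prior on residual precisions; ``a_dl`` the Dirichlet-Laplace
    concentration.
    """

    d: int
    xi2: float = 20.0
    kappa0: float = 0.001
    nu0: float | None = None
    a_alpha: float = 0.1
    b_alpha: float = 0.1
    a_sigma: float = 1.0
    b_sigma: float = 0.3
    a_dl: float = 0.5

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("latent dimension d must be >= 1")
        if self.nu0 is None:
            object.__setattr__(self, "nu0", float(self.d + 50))
        for name in ("xi2", "kappa0", "a_alpha", "b_alpha", "a_sigma", "b_sigma", "a_dl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nu0 <= self.d - 1:
            raise ValueError("nu0 must exceed d - 1")


@dataclass
class DLState:
    """Dirichlet-Laplace local/global scales for vec(Lambda) (length p*d)."""

    psi: np.ndarray  # (p, d) positive local scales
    phi: np.ndarray  # (p, d) positive, sums to one over all entries
    tau: float  # global scale

    def validate(self) -> None:
        if np.any(self.psi <= 0) or np.any(self.phi <= 0) or self.tau <= 0:
            raise ValueError("DL scales must be positive")
        if abs(float(self.phi.sum()) - 1.0) > 1e-12:
            raise ValueError("phi must sum to one")


@dataclass
class ModelState:
    """All Lamb parameters at one MCMC iteration.

    ``labels`` are compact 0-based cluster indices; ``Delta[h]`` is the d x d
    latent covariance of occupied cluster h.  Cluster means and DP weights are
    never instantiated (marginalized analytically / via the CRP).
    """

    Lambda: np.ndarray  # (p, d)
    eta: np.ndarray  # (n, d)
    sigma2: np.ndarray  # (p,)
    labels: np.ndarray  # (n,) int
    Delta: list[np.ndarray]  # per occupied cluster, d x d SPD
    alpha: float
    dl: DLState

    @property
    def n_clusters(self) -> int:
        return len(self.Delta)

    def validate(self) -> None:
        k = self.n_clusters
        counts = np.bincount(self.labels, minlength=k)
        if len(counts) != k or np.any(counts == 0):
            raise ValueError("labels must be compact 0..k-1 with every cluster occupied")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")
        self.dl.validate()


@dataclass(frozen=True)
class FitConfig:
    """MCMC run settings (defaults: 6000 sweeps, 1000 burn-in, thin 5)."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    split_merge_prob: float = 0.5
    n_restricted_scans: int = 5
    seed: int | None = None
    center: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 <= self.split_merge_prob <= 1.0):
            raise ValueError("split_merge_prob must be in [0, 1]")


@dataclass
class FitResult:
    """Retained draws and traces from :func:`fit`."""

    draws: np.ndarray  # (m, n) retained label vectors
    iteration_index: np.ndarray  # (m,)
    alpha_trace: np.ndarray  # (n_iter,)
    kn_trace: np.ndarray  # (n_iter,) int
    loglik_trace: np.ndarray  # (m,)
    d_hat: int
    variance_explained: np.ndarray
    state: ModelState
    data: DataMatrix
    sm_accept_rate: float


# ---------------------------------------------------------------------------
# NIW predictive machinery (eta level, mu0 = 0)
# ---------------------------------------------------------------------------


def _predictive_logpdf_batch(
    x: np.ndarray,
    counts: np.ndarray,
    sums: np.ndarray,
    outers: np.ndarray,
    hp: Hyperparams,
) -> np.ndarray:
    """Log NIW posterior-predictive density of ``x`` for each cluster.

    Cluster h is summarized by (n_h, sum eta, sum eta eta^T); a row with
    n_h = 0 yields the prior predictive.  The predictive is Student-t with
    df = nu_n - d + 1, location mu_n = s/kappa_n and scale
    Psi_n (kappa_n + 1) / (kappa_n (nu_n - d + 1)), where
    Psi_n = xi2 I + sum eta eta^T - s s^T / kappa_n.
    """
    d = x.shape[0]
    kappa_n = hp.kappa0 + counts
    nu_n = hp.nu0 + counts
    df = nu_n - d + 1.0
    if np.any(df <= 0):
        raise ValueError("predictive degrees of freedom must be positive")
    mu_n = sums / kappa_n[:, None]
    Psi = hp.xi2 * np.eye(d)[None] + outers - sums[:, :, None] * sums[:, None, :] / kappa_n[:, None, None]
    scale = Psi * ((kappa_n + 1.0) / (kappa_n * df))[:, None, None]
    try:
        L = np.linalg.cholesky(scale)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(scale + _JITTER * np.eye(d)[None])
    dev = x[None, :] - mu_n
    sol = np.linalg.solve(L, dev[:, :, None])[:, :, 0]
    quad = np.sum(sol**2, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    return (
        gammaln((df + d) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * d * np.log(df * np.pi)
        - 0.5 * logdet
        - 0.5 * (df + d) * np.log1p(quad / df)
    )


def cluster_predictive_logdensity(eta_i: np.ndarray, members: np.ndarray | None, hp: Hyperparams) -> float:
    """Log predictive density of ``eta_i`` given current cluster ``members``.

    ``members`` is an (m, d) array of the latent factors already in the
    cluster (excluding i); ``None`` or an empty array gives the prior
    predictive used for opening a new cluster.
    """
    eta_i = np.atleast_1d(np.asarray(eta_i, dtype=float))
    d = eta_i.shape[0]
    if members is None or len(members) == 0:
        counts = np.zeros(1)
        sums = np.zeros((1, d))
        outers = np.zeros((1, d, d))
    else:
        members = np.atleast_2d(np.asarray(members, dtype=float))
        counts = np.array([float(members.shape[0])])
        sums = members.sum(axis=0)[None]
        outers = (members.T @ members)[None]
    return float(_predictive_logpdf_batch(eta_i, counts, sums, outers, hp)[0])


def _cluster_suffstats(eta: np.ndarray, labels: np.ndarray, k: int):
    """Per-cluster (count, sum, outer-product sum) of the latent factors."""
    n, d = eta.shape
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, d))
    outers = np.zeros((k, d, d))
    for h in range(k):
        mem = eta[labels == h]
        sums[h] = mem.sum(axis=0)
        outers[h] = mem.T @ mem
    return counts, sums, outers


def _draw_delta_conditional(members: np.ndarray, hp: Hyperparams, rng: np.random.Generator) -> np.ndarray:
    """Draw Delta_h ~ IW(psi_hat, nu_hat) given its current members."""
    d = members.shape[1]
    nh = members.shape[0]
    if nh == 0:
        psi_hat = hp.xi2 * np.eye(d)
        nu_hat = hp.nu0
    else:
        eta_bar = members.mean(axis=0)
        dev = members - eta_bar
        psi_hat = (
            hp.xi2 * np.eye(d)
            + dev.T @ dev
            + (hp.kappa0 * nh / (hp.kappa0 + nh)) * np.outer(eta_bar, eta_bar)
        )
        nu_hat = hp.nu0 + nh
    return sample_inverse_wishart(nu_hat, psi_hat, rng)


# ---------------------------------------------------------------------------
# Gibbs steps
# ---------------------------------------------------------------------------


def update_loadings(state: ModelState, data: DataMatrix, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Redraw every row of Lambda from its Gaussian full conditional.

    Row j has precision D_j^{-1} + sigma_j^{-2} eta^T eta with
    D_j = tau^2 diag(psi_j1 phi_j1^2, ..., psi_jd phi_jd^2), and mean
    precision^{-1} eta^T y^(j) / sigma_j^2; all rows are drawn in one
    batched Cholesky pass.
    """
    eta = state.eta
    n, d = eta.shape
    p = data.p
    gram = eta.T @ eta  # (d, d)
    Dinv = 1.0 / (state.dl.tau**2 * state.dl.psi * state.dl.phi**2)  # (p, d)
    prec = gram[None, :, :] / state.sigma2[:, None, None]
    prec[:, np.arange(d), np.arange(d)] += Dinv
    rhs = (data.Y.T @ eta) / state.sigma2[:, None]  # (p, d)
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        prec = prec + _JITTER * np.eye(d)[None]
        L = np.linalg.cholesky(prec)  # raises if still singular
    # mean = prec^{-1} rhs; draw = mean + L^{-T} z
    half = np.linalg.solve(L, rhs[:, :, None])
    mean = np.linalg.solve(np.swapaxes(L, 1, 2), half)[:, :, 0]
    z = rng.standard_normal((p, d, 1))
    noise = np.linalg.solve(np.swapaxes(L, 1, 2), z)[:, :, 0]
    state.Lambda = mean + noise
    return state


def update_cluster_covariances(state: ModelState, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Redraw every occupied cluster covariance Delta_h from IW(psi_hat, nu_hat)."""
    k = state.n_clusters
    counts = np.bincount(state.labels, minlength=k)
    if np.any(counts == 0):
        raise RuntimeError("empty cluster encountered; labels must be compacted first")
    for h in range(k):
        members = state.eta[state.labels == h]
        state.Delta[h] = _draw_delta_conditional(members, hp, rng)
    return state


def update_latent_factors(state: ModelState, data: DataMatrix, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Sequentially redraw each eta_i from its location-marginalized conditional.

    With the cluster mean integrated out, the prior of eta_i given the other
    members of its cluster is N(mu_hat_{h,-i}, (1 + 1/kappa_hat_{h,-i}) Delta_h)
    with kappa_hat = kappa0 + n_{h,-i} and mu_hat = n_{h,-i} eta_bar_{h,-i} /
    (kappa0 + n_{h,-i}); combining with the likelihood of y_i gives a Gaussian
    with precision Lambda^T Sigma^{-1} Lambda + {(1+1/kappa_hat) Delta_h}^{-1}.
    """
    n, d = state.eta.shape
    Lam = state.Lambda
    A = (Lam / state.sigma2[:, None]).T @ Lam  # Lambda^T Sigma^-1 Lambda
    R = data.Y @ (Lam / state.sigma2[:, None])  # (n, d): rows Lambda^T Sigma^-1 y_i
    k = state.n_clusters
    counts = np.bincount(state.labels, minlength=k).astype(float)
    sums = np.zeros((k, d))
    for h in range(k):
        sums[h] = state.eta[state.labels == h].sum(axis=0)

    # per-cluster constants: all members of cluster h share kappa_hat and the
    # posterior covariance (it does not depend on eta)
    cov = [None] * k
    chol_cov = [None] * k
    prior_prec = [None] * k
    for h in range(k):
        kap = hp.kappa0 + counts[h] - 1.0
        c = kap / (kap + 1.0)
        Dinv = np.linalg.inv(state.Delta[h])
        P = A + c * Dinv
        try:
            cov[h] = np.linalg.inv(P)
            chol_cov[h] = np.linalg.cholesky(cov[h])
        except np.linalg.LinAlgError:
            cov[h] = np.linalg.inv(P + _JITTER * np.eye(d))
            chol_cov[h] = np.linalg.cholesky(cov[h])
        prior_prec[h] = c * Dinv

    z = rng.standard_normal((n, d))
    for i in range(n):
        h = int(state.labels[i])
        kap = hp.kappa0 + counts[h] - 1.0
        mu_hat = (sums[h] - state.eta[i]) / kap if counts[h] > 1 else np.zeros(d)
        rho = R[i] + prior_prec[h] @ mu_hat
        mean = cov[h] @ rho
        new = mean + chol_cov[h] @ z[i]
        sums[h] += new - state.eta[i]
        state.eta[i] = new
    return state


def update_labels(state: ModelState, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Sequential CRP scan of the cluster labels (collapsed over mu_h, Delta_h).

    Each c_i is resampled over occupied clusters (weight n_{h,-i} times the
    NIW posterior predictive of eta_i) plus a new cluster (weight alpha times
    the prior predictive); probabilities normalized in log space inside the
    compiled kernel.  Emptied clusters are deleted and labels compacted;
    clusters opened during the scan receive Delta_h from their Step-2
    conditional given their members.
    """
    from ._kernels import crp_scan

    n, d = state.eta.shape
    k = state.n_clusters
    cap = n + 1
    counts = np.zeros(cap)
    sums = np.zeros((cap, d))
    outers = np.zeros((cap, d, d))
    c0, s0, o0 = _cluster_suffstats(state.eta, state.labels, k)
    counts[:k], sums[:k], outers[:k] = c0, s0, o0
    ids = np.full(cap, -1, dtype=np.int64)
    ids[:k] = np.arange(k)
    labels = np.ascontiguousarray(state.labels, dtype=np.int64)
    eta = np.ascontiguousarray(state.eta)
    k_new = int(
        crp_scan(
            eta, labels, ids, counts, sums, outers, k,
            float(state.alpha), hp.kappa0, hp.nu0, hp.xi2, rng,
        )
    )
    new_delta: list[np.ndarray] = []
    for h in range(k_new):
        if ids[h] >= 0:
            new_delta.append(state.Delta[int(ids[h])])
        else:
            new_delta.append(_draw_delta_conditional(eta[labels == h], hp, rng))
    state.labels = labels
    state.Delta = new_delta
    return state


def update_concentration(state: ModelState, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Escobar-West auxiliary update of the DP concentration alpha."""
    n = state.labels.shape[0]
    r = state.n_clusters
    phi = rng.beta(state.alpha + 1.0, n)
    rate = hp.b_alpha - np.log(phi)
    odds = (hp.a_alpha + r - 1.0) / (n * rate)
    pi = odds / (1.0 + odds)
    if rng.random() < pi:
        shape = hp.a_alpha + r
    else:
        shape = hp.a_alpha + r - 1.0
    state.alpha = float(rng.gamma(shape=shape, scale=1.0 / rate))
    return state


def update_residual_variances(state: ModelState, data: DataMatrix, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Redraw residual precisions from their gamma full conditionals."""
    n = data.n
    resid = data.Y - state.eta @ state.Lambda.T
    ssr = np.sum(resid**2, axis=0)
    shape = hp.a_sigma + 0.5 * n
    rate = hp.b_sigma + 0.5 * ssr
    prec = rng.gamma(shape=shape, scale=1.0 / rate)
    state.sigma2 = 1.0 / prec
    return state


def update_dl_hyperparameters(state: ModelState, hp: Hyperparams, rng: np.random.Generator) -> ModelState:
    """Block-draw the Dirichlet-Laplace scales (phi, tau, psi) given Lambda.

    The joint conditional factorizes as p(phi | Lambda) p(tau | phi, Lambda)
    p(psi | phi, tau, Lambda) and is sampled in that order: T_jh ~
    giG(a - 1, 1, 2|lambda_jh|) with phi = T / sum T; tau ~
    giG(pd(a - 1), 1, 2 sum |lambda_jh| / phi_jh); and 1/psi_jh ~
    iG(tau phi_jh / |lambda_jh|, 1).
    """
    a = hp.a_dl
    absL = np.maximum(np.abs(state.Lambda), _ABS_FLOOR)
    p, d = absL.shape
    m = p * d
    # phi | Lambda
    T = sample_gig_vector(a - 1.0, 2.0 * absL.ravel(), rng).reshape(p, d)
    phi = T / T.sum()
    phi = np.maximum(phi, 1e-300)
    phi = phi / phi.sum()
    # tau | phi, Lambda
    tau = float(sample_gig(GIGParams(m * (a - 1.0), 1.0, 2.0 * float(np.sum(absL / phi))), rng))
    # psi | phi, tau, Lambda
    psi_tilde = sample_inverse_gaussian(tau * phi / absL, 1.0, rng)
    psi = 1.0 / np.maximum(psi_tilde, 1e-300)
    state.dl = DLState(psi=psi, phi=phi, tau=tau)
    return state


def log_likelihood(state: ModelState, data: DataMatrix) -> float:
    """Gaussian measurement log-likelihood log p(Y | Lambda, eta, Sigma)."""
    resid = data.Y - state.eta @ state.Lambda.T
    n = data.n
    return float(
        -0.5 * n * np.sum(np.log(2.0 * np.pi * state.sigma2))
        - 0.5 * np.sum(resid**2 / state.sigma2[None, :])
    )


def gibbs_sweep(
    state: ModelState,
    data: DataMatrix,
    hp: Hyperparams,
    cfg: FitConfig,
    rng: np.random.Generator,
) -> tuple[ModelState, bool | None]:
    """One full Gibbs scan, then a split-merge attempt with configured probability.

    Returns the state and the split-merge acceptance flag (``None`` when no
    attempt was made this sweep).
    """
    from .splitmerge import SplitMergeConfig, propose_and_accept

    state = update_loadings(state, data, hp, rng)
    state = update_cluster_covariances(state, hp, rng)
    state = update_latent_factors(state, data, hp, rng)
    state = update_labels(state, hp, rng)
    state = update_concentration(state, hp, rng)
    state = update_residual_variances(state, data, hp, rng)
    state = update_dl_hyperparameters(state, hp, rng)
    accepted: bool | None = None
    if cfg.split_merge_prob > 0 and rng.random() < cfg.split_merge_prob:
        state, accepted = propose_and_accept(
            state, hp, SplitMergeConfig(n_restricted_scans=cfg.n_restricted_scans), rng
        )
    return state, accepted


# ---------------------------------------------------------------------------
# prior simulation (used for joint-distribution validation and prior-only chains)
# ---------------------------------------------------------------------------


def sample_prior_state(hp: Hyperparams, n: int, p: int, rng: np.random.Generator) -> ModelState:
    """Draw a full model state from the prior (cluster means marginalized out).

    Labels follow the CRP given alpha ~ Ga(a_alpha, b_alpha); each occupied
    cluster receives Delta_h ~ IW(nu0, xi2 I); latent factors are simulated by
    instantiating the cluster mean mu_h ~ N(0, Delta_h / kappa0) and then
    discarding it.  The Dirichlet-Laplace hierarchy is simulated forward.
    """
    d = hp.d
    alpha = float(rng.gamma(shape=hp.a_alpha, scale=1.0 / hp.b_alpha))
    labels = np.zeros(n, dtype=int)
    counts: list[int] = []
    for i in range(n):
        if i == 0:
            labels[i] = 0
            counts = [1]
            continue
        w = np.array(counts + [alpha], dtype=float)
        w /= w.sum()
        choice = int(rng.choice(len(w), p=w))
        if choice == len(counts):
            counts.append(1)
        else:
            counts[choice] += 1
        labels[i] = choice
    k = len(counts)
    Delta = [sample_inverse_wishart(hp.nu0, hp.xi2 * np.eye(d), rng) for _ in range(k)]
    eta = np.zeros((n, d))
    for h in range(k):
        Lh = np.linalg.cholesky(Delta[h])
        mu_h = Lh @ rng.standard_normal(d) / np.sqrt(hp.kappa0)
        idx = np.where(labels == h)[0]
        eta[idx] = mu_h[None, :] + rng.standard_normal((len(idx), d)) @ Lh.T
    # Dirichlet-Laplace forward simulation on vec(Lambda)
    m = p * d
    phi = rng.dirichlet(np.full(m, hp.a_dl)).reshape(p, d)
    phi = np.maximum(phi, 1e-300)
    phi /= phi.sum()
    tau = float(rng.gamma(shape=m * hp.a_dl, scale=2.0))
    psi = rng.exponential(scale=2.0, size=(p, d))
    Lambda = rng.standard_normal((p, d)) * np.sqrt(psi) * phi * tau
    sigma2 = 1.0 / rng.gamma(shape=hp.a_sigma, scale=1.0 / hp.b_sigma, size=p)
    return ModelState(
        Lambda=Lambda,
        eta=eta,
        sigma2=sigma2,
        labels=labels,
        Delta=Delta,
        alpha=alpha,
        dl=DLState(psi=psi, phi=phi, tau=tau),
    )


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


def _initial_state(
    data: DataMatrix,
    hp: Hyperparams,
    init,
    rng: np.random.Generator,
) -> ModelState:
    n, p = data.Y.shape
    d = hp.d
    eta = np.asarray(init.eta0[:, :d], dtype=float).copy()
    Lambda = np.asarray(init.Lambda0[:, :d], dtype=float).copy()
    labels = np.asarray(init.labels0, dtype=int).copy()
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    k = int(labels.max()) + 1
    Delta = [_draw_delta_conditional(eta[labels == h], hp, rng) for h in range(k)]
    resid = data.Y - eta @ Lambda.T
    sigma2 = np.maximum(np.mean(resid**2, axis=0), 1e-6)
    m = p * d
    dl = DLState(psi=np.ones((p, d)), phi=np.full((p, d), 1.0 / m), tau=float(m * hp.a_dl * 2.0))
    return ModelState(
        Lambda=Lambda, eta=eta, sigma2=sigma2, labels=labels, Delta=Delta, alpha=1.0, dl=dl
    )


def fit(
    data: DataMatrix,
    hp: Hyperparams | None = None,
    cfg: FitConfig | None = None,
    var_threshold: float = 0.95,
    callback: Callable[[int, ModelState], None] | None = None,
) -> FitResult:
    """Run dimension selection, initialization, and the full MCMC.

    When ``hp`` is ``None`` (or ``hp.d`` should be learned), the latent
    dimension is chosen empirically as the smallest d whose leading singular
    values explain at least ``var_threshold`` of the variance.  Retains
    post-burn-in thinned label vectors plus alpha / kn / log-likelihood
    traces.  ``callback(iteration, state)`` runs at every retained draw.
    """
    from .initialize import kmeans_init, select_dimension

    cfg = cfg or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    if cfg.center:
        Yc = data.Y - data.Y.mean(axis=0, keepdims=True)
        data = DataMatrix(Yc, row_names=data.row_names, col_names=data.col_names)
    init = select_dimension(data, threshold=var_threshold, run_kmeans=False)
    if hp is None:
        hp = Hyperparams(d=init.d_hat)
    d = hp.d
    if d >= data.n:
        raise ValueError(f"latent dimension d={d} must be smaller than n={data.n}")
    if d != init.d_hat:
        init = select_dimension(
            data, threshold=var_threshold, r_max=max(d, 1), force_d=d, run_kmeans=False
        )
    init.labels0 = kmeans_init(init.eta0, rng=rng)
    state = _initial_state(data, hp, init, rng)
    logger.info("fit: n=%d p=%d d=%d k_init=%d", data.n, data.p, d, state.n_clusters)

    m_expected = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    draws = np.zeros((m_expected, data.n), dtype=int)
    iter_idx = np.zeros(m_expected, dtype=int)
    loglik = np.zeros(m_expected)
    alpha_trace = np.zeros(cfg.n_iter)
    kn_trace = np.zeros(cfg.n_iter, dtype=int)
    sm_attempts = 0
    sm_accepts = 0
    m = 0
    for it in range(cfg.n_iter):
        state, accepted = gibbs_sweep(state, data, hp, cfg, rng)
        if accepted is not None:
            sm_attempts += 1
            sm_accepts += int(accepted)
        alpha_trace[it] = state.alpha
        kn_trace[it] = state.n_clusters
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            draws[m] = state.labels
            iter_idx[m] = it
            loglik[m] = log_likelihood(state, data)
            if callback is not None:
                callback(it, state)
            m += 1
        if (it + 1) % 1000 == 0:
            lo = max(0, it - 999)
            logger.info(
                "iter %d: kn mean %.2f (last 1000), alpha %.3f, split-merge acc %.2f",
                it + 1,
                float(kn_trace[lo : it + 1].mean()),
                state.alpha,
                sm_accepts / max(sm_attempts, 1),
            )
    return FitResult(
        draws=draws[:m],
        iteration_index=iter_idx[:m],
        alpha_trace=alpha_trace,
        kn_trace=kn_trace,
        loglik_trace=loglik[:m],
        d_hat=int(init.d_hat),
        variance_explained=np.asarray(init.variance_explained),
        state=state,
        data=data,
        sm_accept_rate=sm_accepts / max(sm_attempts, 1),
    )
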
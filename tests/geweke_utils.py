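"""Joint-distribution (Geweke-style) validation harnesses shared by the tests.

Two complementary designs:

* ``single_update_zscores``: draw a fresh state from the prior at every
  iteration, resimulate data, apply one update, and compare monitor means
  against pure prior draws.  Draws are i.i.d., so the comparison is exact and
  has full power per iteration; it validates each conditional separately at
  any hyperparameter setting (including the heavy-tailed defaults).
* ``chain_zscores``: the successive-conditional chain (resimulate data, full
  sweep, repeat) whose time averages must match the prior; run at
  hyperparameters under which the chain actually mixes, with batch-means
  standard errors.
"""

from __future__ import annotations

import numpy as np

from lambclust.model import (
    DataMatrix,
    FitConfig,
    Hyperparams,
    gibbs_sweep,
    sample_prior_state,
)

MONITOR_NAMES = [
    "kn",
    "log_alpha",
    "log_tau",
    "mean_log_sigma2",
    "mean_abs_lambda",
    "log_mean_eta2",
    "mean_lambda2",
    "log_mean_psi",
]


def monitors(state) -> np.ndarray:
    return np.array(
        [
            state.n_clusters,
            np.log(state.alpha),
            np.log(state.dl.tau),
            np.mean(np.log(state.sigma2)),
            np.mean(np.abs(state.Lambda)),
            np.log(np.mean(state.eta**2)),
            np.mean(state.Lambda**2),
            np.log(np.mean(state.dl.psi)),
        ]
    )


def resimulate_data(state, n: int, p: int, rng: np.random.Generator) -> DataMatrix:
    Y = state.eta @ state.Lambda.T + rng.standard_normal((n, p)) * np.sqrt(state.sigma2)[None, :]
    return DataMatrix(Y)


def batch_se(x: np.ndarray, nbatch: int = 40) -> float:
    m = len(x) // nbatch
    bm = x[: m * nbatch].reshape(nbatch, m).mean(axis=1)
    return float(bm.std(ddof=1) / np.sqrt(nbatch))


def mcmc_se(x: np.ndarray) -> float:
    """Time-average standard error via Geyer's initial monotone positive
    sequence estimate of the integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * m)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: m // 2].real / m
    if acov[0] <= 0:
        return 0.0
    rho = acov / acov[0]
    # pairwise sums Gamma_k = rho_{2k} + rho_{2k+1}, truncated at the first
    # negative pair, then forced nonincreasing
    gammas = []
    k = 0
    while 2 * k + 1 < len(rho):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        gammas.append(g)
        k += 1
    for i in range(1, len(gammas)):
        gammas[i] = min(gammas[i], gammas[i - 1])
    iact = max(-1.0 + 2.0 * sum(gammas), 1.0)
    return float(np.sqrt(acov[0] * iact / m))


def single_update_zscores(
    update,
    hp: Hyperparams,
    n: int,
    p: int,
    n_iter: int,
    seed: int,
) -> np.ndarray:
    """z-scores of monitor means after one ``update(state, data, rng)`` applied
    to an exact prior draw, against pure prior draws (i.i.d. comparison)."""
    rng = np.random.default_rng(seed)
    prior = np.zeros((n_iter, len(MONITOR_NAMES)))
    post = np.zeros_like(prior)
    for it in range(n_iter):
        state = sample_prior_state(hp, n, p, rng)
        prior[it] = monitors(state)
        data = resimulate_data(state, n, p, rng)
        state = update(state, data, rng)
        post[it] = monitors(state)
    se = np.sqrt(prior.var(axis=0, ddof=1) / n_iter + post.var(axis=0, ddof=1) / n_iter)
    return (post.mean(axis=0) - prior.mean(axis=0)) / se


def chain_zscores(
    hp: Hyperparams,
    n: int,
    p: int,
    n_replicates: int,
    sweeps_per_replicate: int,
    seed: int,
    split_merge_prob: float = 0.5,
    n_restricted_scans: int = 3,
) -> np.ndarray:
    """Replicated successive-conditional chains vs prior draws.

    Each replicate starts from an exact prior draw and alternates data
    resimulation with full Gibbs + split-merge sweeps; if every sweep
    preserves the joint, the final state of each replicate is again an exact
    prior draw, and replicates are independent — so the comparison has i.i.d.
    power while still exercising error accumulation across sweeps (a single
    long chain is useless here: the shrinkage hierarchy's autocorrelation
    time under informative resimulated data exceeds any affordable chain).
    """
    cfg = FitConfig(
        n_iter=2,
        burn_in=0,
        thin=1,
        split_merge_prob=split_merge_prob,
        n_restricted_scans=n_restricted_scans,
    )
    rng = np.random.default_rng(seed)
    prior = np.zeros((n_replicates, len(MONITOR_NAMES)))
    final = np.zeros_like(prior)
    for r in range(n_replicates):
        state = sample_prior_state(hp, n, p, rng)
        prior[r] = monitors(state)
        for _ in range(sweeps_per_replicate):
            data = resimulate_data(state, n, p, rng)
            state, _ = gibbs_sweep(state, data, hp, cfg, rng)
        final[r] = monitors(state)
    se = np.sqrt(
        prior.var(axis=0, ddof=1) / n_replicates + final.var(axis=0, ddof=1) / n_replicates
    )
    return (final.mean(axis=0) - prior.mean(axis=0)) / se


def geweke_friendly_hyperparams(d: int) -> Hyperparams:
    """Hyperparameters under which the successive-conditional chain mixes.

    The model defaults (kappa0 = 0.001, alpha ~ Ga(0.1, 0.1)) make the chain
    metastable (the one-cluster regime persists for >> 10^4 sweeps), which
    starves the time-average test of effective samples without being wrong;
    the conditionals under test are identical code paths at any setting.
    """
    return Hyperparams(
        d=d, xi2=2.0, kappa0=1.0, nu0=d + 4.0,
        a_alpha=1.0, b_alpha=1.0, a_sigma=2.0, b_sigma=1.0, a_dl=0.5,
    )
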
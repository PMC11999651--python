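"""Jain-Neal split-merge Metropolis-Hastings move on the latent-level DP mixture.

The move picks two anchor items uniformly; co-clustered anchors trigger a
split proposal grown from a random launch state by restricted Gibbs scans
(allocation restricted to the two candidate clusters, with the same
marginalized NIW predictive probabilities as the main label scan), otherwise
the merge of the two clusters is proposed.  The acceptance ratio combines
the DP partition prior factor, the marginalized NIW likelihoods of the
affected blocks, and the restricted-scan proposal probability, all in log
space (exp only at the final accept/reject comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._kernels import block_log_marginal, restricted_scan_kernel
from .model import Hyperparams, ModelState, _draw_delta_conditional

__all__ = ["SplitMergeConfig", "propose_and_accept", "restricted_scan"]


@dataclass(frozen=True)
class SplitMergeConfig:
    """Number of intermediate restricted Gibbs scans used to build the launch state."""

    n_restricted_scans: int = 5

    def __post_init__(self) -> None:
        if self.n_restricted_scans < 1:
            raise ValueError("n_restricted_scans must be >= 1")


def _stats_for(eta: np.ndarray, members0: list[int], members1: list[int]):
    d = eta.shape[1]
    counts = np.array([float(len(members0)), float(len(members1))])
    sums = np.zeros((2, d))
    outers = np.zeros((2, d, d))
    for c, mem in ((0, members0), (1, members1)):
        if mem:
            block = eta[mem]
            sums[c] = block.sum(axis=0)
            outers[c] = block.T @ block
    return counts, sums, outers


def restricted_scan(
    free_items: list[int] | np.ndarray,
    assign: np.ndarray,
    eta: np.ndarray,
    stats: tuple[np.ndarray, np.ndarray, np.ndarray],
    hp: Hyperparams,
    rng: np.random.Generator | None = None,
    target: np.ndarray | None = None,
) -> float:
    """One restricted Gibbs scan over the free items; returns its log probability.

    Each free item is reassigned between the two candidate clusters with the
    marginalized NIW predictive probabilities given the current restricted
    configuration; ``assign`` (length n, entries 0/1 for the items involved)
    and ``stats`` are updated in place.  With ``target`` given, no sampling
    occurs: the scan is forced through ``target`` and the value is the log
    probability of producing exactly that configuration (the reverse-move
    density of a merge proposal).  Zero free items give log-probability 0.
    """
    items = np.asarray(free_items, dtype=np.int64)
    counts, sums, outers = stats
    forced = target is not None
    tgt = target if forced else np.zeros(1, dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(0)
    return float(
        restricted_scan_kernel(
            np.ascontiguousarray(eta), items, assign, counts, sums, outers,
            hp.kappa0, hp.nu0, hp.xi2, rng, forced, tgt,
        )
    )


def _block_log_marginal(eta: np.ndarray, idx, hp: Hyperparams) -> float:
    return float(block_log_marginal(np.ascontiguousarray(eta[idx]), hp.kappa0, hp.nu0, hp.xi2))


def _build_launch(
    eta: np.ndarray,
    i: int,
    j: int,
    free: list[int],
    hp: Hyperparams,
    cfg: SplitMergeConfig,
    rng: np.random.Generator,
):
    """Random launch state: anchors fixed to distinct clusters, free items
    assigned uniformly, then ``n_restricted_scans`` restricted scans."""
    n = eta.shape[0]
    assign = np.zeros(n, dtype=np.int64)
    assign[i] = 0
    assign[j] = 1
    members0, members1 = [i], [j]
    for l in free:
        c = int(rng.random() < 0.5)
        assign[l] = c
        (members0 if c == 0 else members1).append(l)
    stats = _stats_for(eta, members0, members1)
    for _ in range(cfg.n_restricted_scans):
        restricted_scan(free, assign, eta, stats, hp, rng)
    return assign, stats


def propose_and_accept(
    state: ModelState,
    hp: Hyperparams,
    cfg: SplitMergeConfig,
    rng: np.random.Generator,
) -> tuple[ModelState, bool]:
    """One split-merge attempt; returns (state, accepted).

    A rejected proposal returns the input state unchanged (the flag still
    reports the attempt).
    """
    n = state.labels.shape[0]
    if n < 2:
        return state, False
    eta = state.eta
    labels = state.labels
    i, j = (int(v) for v in rng.choice(n, size=2, replace=False))
    ci, cj = int(labels[i]), int(labels[j])
    if ci == cj:
        # ----- split proposal -----
        block = [int(l) for l in np.where(labels == ci)[0]]
        free = [l for l in block if l not in (i, j)]
        assign, stats = _build_launch(eta, i, j, free, hp, cfg, rng)
        logq = restricted_scan(free, assign, eta, stats, hp, rng)  # final scan: the proposal
        new_a = [i] + [l for l in free if assign[l] == 0]
        new_b = [j] + [l for l in free if assign[l] == 1]
        log_prior = float(
            np.log(state.alpha) + gammaln(len(new_a)) + gammaln(len(new_b)) - gammaln(len(block))
        )
        log_lik = (
            _block_log_marginal(eta, new_a, hp)
            + _block_log_marginal(eta, new_b, hp)
            - _block_log_marginal(eta, block, hp)
        )
        log_ratio = log_prior + log_lik - logq
        if np.log(rng.random()) < log_ratio:
            new_label = state.n_clusters
            for l in new_b:
                labels[l] = new_label
            state.Delta[ci] = _draw_delta_conditional(eta[new_a], hp, rng)
            state.Delta.append(_draw_delta_conditional(eta[new_b], hp, rng))
            return state, True
        return state, False
    # ----- merge proposal -----
    block_a = [int(l) for l in np.where(labels == ci)[0]]
    block_b = [int(l) for l in np.where(labels == cj)[0]]
    merged = block_a + block_b
    free = [l for l in merged if l not in (i, j)]
    assign, stats = _build_launch(eta, i, j, free, hp, cfg, rng)
    target = np.zeros(n, dtype=np.int64)
    for l in free:
        target[l] = 0 if int(labels[l]) == ci else 1
    logq_rev = restricted_scan(free, assign, eta, stats, hp, rng, target=target)
    log_prior = float(
        gammaln(len(merged)) - np.log(state.alpha) - gammaln(len(block_a)) - gammaln(len(block_b))
    )
    log_lik = (
        _block_log_marginal(eta, merged, hp)
        - _block_log_marginal(eta, block_a, hp)
        - _block_log_marginal(eta, block_b, hp)
    )
    log_ratio = log_prior + log_lik + logq_rev
    if np.log(rng.random()) < log_ratio:
        keep, drop = (ci, cj) if ci < cj else (cj, ci)
        labels[labels == drop] = keep
        last = state.n_clusters - 1
        if drop != last:
            labels[labels == last] = drop
            state.Delta[drop] = state.Delta[last]
        state.Delta.pop()
        state.Delta[keep] = _draw_delta_conditional(eta[merged], hp, rng)
        return state, True
    return state, False
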
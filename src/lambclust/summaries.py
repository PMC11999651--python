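"""Posterior partition summaries.

Given the retained label vectors from the sampler: the posterior similarity
matrix of pairwise co-clustering frequencies, the Binder-loss point estimate
(minimized over visited partitions), the adjusted Rand index, the posterior
distribution of the number of occupied clusters, and equal-tailed credible
intervals for the ARI against a reference labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "PartitionDraws",
    "SimilarityMatrix",
    "similarity_matrix",
    "binder_point_estimate",
    "adjusted_rand_index",
    "posterior_cluster_count",
    "ari_credible_interval",
]


@dataclass
class PartitionDraws:
    """Retained MCMC label vectors: an m x n integer matrix plus iteration indices."""

    draws: np.ndarray
    iteration_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=int))
        if self.draws.shape[0] < 1:
            raise ValueError("need at least one retained draw")
        if self.iteration_index is None:
            self.iteration_index = np.arange(self.draws.shape[0])
        self.iteration_index = np.asarray(self.iteration_index, dtype=int)

    @property
    def m(self) -> int:
        return self.draws.shape[0]

    @property
    def n(self) -> int:
        return self.draws.shape[1]


@dataclass
class SimilarityMatrix:
    """n x n matrix of posterior co-clustering frequencies."""

    P: np.ndarray


def _as_draws(draws) -> PartitionDraws:
    if isinstance(draws, PartitionDraws):
        return draws
    return PartitionDraws(np.asarray(draws))


def similarity_matrix(draws) -> SimilarityMatrix:
    """P[i, j] = fraction of retained draws in which i and j share a cluster."""
    draws = _as_draws(draws)
    m, n = draws.m, draws.n
    P = np.zeros((n, n))
    for labels in draws.draws:
        P += labels[:, None] == labels[None, :]
    P /= m
    return SimilarityMatrix(P=P)


def _binder_loss(labels: np.ndarray, P: np.ndarray) -> float:
    """Posterior-expected equal-cost Binder loss of one partition: sum_{i<j} |1{ci=cj} - P_ij|."""
    co = (labels[:, None] == labels[None, :]).astype(float)
    diff = np.abs(co - P)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    return float(diff[iu].sum())


def binder_point_estimate(draws, P: SimilarityMatrix | np.ndarray | None = None) -> np.ndarray:
    """The visited partition minimizing the posterior-expected Binder loss.

    Ties are broken by earliest iteration (first minimizer in draw order).
    """
    draws = _as_draws(draws)
    if P is None:
        P = similarity_matrix(draws)
    Pm = P.P if isinstance(P, SimilarityMatrix) else np.asarray(P)
    losses = np.array([_binder_loss(labels, Pm) for labels in draws.draws])
    return draws.draws[int(np.argmin(losses))].copy()


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index; 1 for identical partitions up to relabeling."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def posterior_cluster_count(draws) -> tuple[np.ndarray, np.ndarray]:
    """Posterior distribution of the number of occupied clusters k_n.

    Returns (values, probabilities) over the observed counts.
    """
    draws = _as_draws(draws)
    kn = np.array([len(np.unique(labels)) for labels in draws.draws])
    values, counts = np.unique(kn, return_counts=True)
    return values, counts / draws.m


def ari_credible_interval(draws, reference, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval for the ARI of each draw vs a reference."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    draws = _as_draws(draws)
    reference = np.asarray(reference)
    aris = np.array([adjusted_rand_index(labels, reference) for labels in draws.draws])
    lo = (1.0 - level) / 2.0
    return float(np.quantile(aris, lo)), float(np.quantile(aris, 1.0 - lo))
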
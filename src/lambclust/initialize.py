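"""Empirical-Bayes latent-dimension choice and initialization of the sampler.

The latent dimension is set to the smallest number of leading singular values
of the column-centered data explaining at least 95% of the total variance
(truncated Lanczos SVD for large matrices, exact SVD otherwise); the singular
triplets initialize the loadings and factors, and k-means on the factors
initializes the cluster labels with k chosen by average silhouette width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd as dense_svd
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import DataMatrix

__all__ = ["InitResult", "select_dimension", "kmeans_init"]

logger = logging.getLogger("lambclust")


@dataclass
class InitResult:
    """Latent dimension estimate plus SVD- and k-means-based starting values."""

    d_hat: int
    Lambda0: np.ndarray  # (p, d_hat)
    eta0: np.ndarray  # (n, d_hat)
    labels0: np.ndarray  # (n,)
    variance_explained: np.ndarray  # cumulative ratios, length = #components computed


def select_dimension(
    data: DataMatrix,
    threshold: float = 0.95,
    r_max: int | None = None,
    center: bool = True,
    force_d: int | None = None,
    seed: int = 0,
    run_kmeans: bool = True,
) -> InitResult:
    """Choose d as the smallest dimension explaining ``threshold`` of the variance.

    The variance denominator is the full squared Frobenius norm of the
    (column-centered) data, so the cumulative ratios are exact even when only
    ``r_max`` singular values are computed; if the threshold is unreachable
    within ``r_max`` components, ``r_max`` is returned with a warning.
    Scaling convention: ``Lambda0 = V_d diag(s_d)/sqrt(n)`` and
    ``eta0 = sqrt(n) U_d`` so that the initial factors satisfy
    ``eta0^T eta0 = n I``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    Y = data.Y
    n, p = Y.shape
    if center:
        Y = Y - Y.mean(axis=0, keepdims=True)
    total = float(np.sum(Y**2))
    if total <= 0:
        raise ValueError("data matrix is constant: zero variance")
    if r_max is None:
        r_max = min(n, p, 200)
    r_max = min(r_max, n, p)
    if force_d is not None:
        r_max = max(r_max, force_d)
    if min(n, p) <= 200 or r_max >= min(n, p) - 1:
        U, s, Vt = dense_svd(Y, full_matrices=False)
        U, s, Vt = U[:, :r_max], s[:r_max], Vt[:r_max]
    else:
        # augmented implicitly restarted Lanczos bidiagonalization
        U, s, Vt = svds(Y, k=r_max, random_state=seed)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    cum = np.cumsum(s**2) / total
    if force_d is not None:
        d_hat = int(force_d)
    else:
        reached = np.nonzero(cum >= threshold)[0]
        if len(reached) == 0:
            logger.warning(
                "variance threshold %.3f unreachable within r_max=%d (reached %.3f); using d=%d",
                threshold,
                r_max,
                cum[-1],
                r_max,
            )
            d_hat = int(r_max)
        else:
            d_hat = int(reached[0]) + 1
    Lambda0 = (Vt[:d_hat].T * s[:d_hat]) / np.sqrt(n)
    eta0 = np.sqrt(n) * U[:, :d_hat]
    if run_kmeans:
        labels0 = kmeans_init(eta0, rng=np.random.default_rng(seed))
    else:
        labels0 = np.zeros(n, dtype=int)
    logger.info("selected d_hat=%d (cumulative variance %.4f)", d_hat, cum[d_hat - 1])
    return InitResult(
        d_hat=d_hat, Lambda0=Lambda0, eta0=eta0, labels0=labels0, variance_explained=cum
    )


def kmeans_init(
    eta0: np.ndarray,
    k_grid: range | list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """K-means labels on the initial factors, k chosen by average silhouette width.

    Default grid is 2..min(20, n-1); a single-element grid forces that k.
    Deterministic given the seed derived from ``rng``.
    """
    eta0 = np.atleast_2d(np.asarray(eta0, dtype=float))
    n = eta0.shape[0]
    if n < 2:
        raise ValueError("k-means initialization needs n >= 2")
    if k_grid is None:
        k_grid = range(2, min(20, n - 1) + 1)
    k_grid = [int(k) for k in k_grid if 2 <= k <= n - 1] or [min(2, n - 1)]
    rng = rng or np.random.default_rng(0)
    seed = int(rng.integers(0, 2**31 - 1))
    best_labels, best_score = None, -np.inf
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(eta0)
        if len(np.unique(labels)) < 2:
            continue
        if len(k_grid) == 1:
            return labels
        score = silhouette_score(eta0, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    if best_labels is None:
        return np.zeros(n, dtype=int)
    return best_labels
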
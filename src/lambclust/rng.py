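"""Special random-variate generators and log-densities used by the sampler.

All samplers take an explicit :class:`numpy.random.Generator` and are exactly
reproducible given the stream.  Parameterizations used throughout the package:

* inverse-Gaussian ``iG(mu, lam)`` with mean ``mu`` and shape ``lam``;
* generalized inverse Gaussian ``giG(lam, rho, chi)`` with density
  proportional to ``x**(lam-1) * exp(-(rho*x + chi/x)/2)`` on ``x > 0``;
* inverse-Wishart ``IW(df, scale)`` with mean ``scale/(df-d-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.linalg import solve_triangular

__all__ = [
    "GIGParams",
    "StudentTParams",
    "sample_inverse_gaussian",
    "sample_gig",
    "sample_gig_vector",
    "gig_logpdf",
    "sample_inverse_wishart",
    "logpdf_mvt",
    "log_multigamma",
    "spawn_stream",
]

# Below this, a GIG chi (or rho) parameter is treated as exactly at the
# gamma (or inverse-gamma) boundary of the family.
_GIG_BOUNDARY = 1e-300


def spawn_stream(rng: np.random.Generator, key: int) -> np.random.Generator:
    """Deterministically derive an independent substream from ``rng``.

    A single root seed is split per component so that tests of one module do
    not depend on how many draws another module consumed.
    """
    root = rng.integers(0, 2**63 - 1)
    return np.random.default_rng(np.random.SeedSequence([int(root), int(key)]))


@dataclass(frozen=True)
class GIGParams:
    """Parameters of the generalized inverse Gaussian law.

    Density proportional to ``x**(lam-1) * exp(-(rho*x + chi/x)/2)``.
    ``chi = 0`` requires ``lam > 0`` (gamma limit); ``rho = 0`` requires
    ``lam < 0`` (inverse-gamma limit).
    """

    lam: float
    rho: float
    chi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ValueError("GIG order parameter must be finite")
        if self.rho < 0 or not np.isfinite(self.rho):
            raise ValueError("GIG rho must be finite and >= 0")
        if self.chi < 0 or not np.isfinite(self.chi):
            raise ValueError("GIG chi must be finite and >= 0")
        if self.chi <= _GIG_BOUNDARY and self.lam <= 0:
            raise ValueError("GIG with chi=0 requires lam > 0 (gamma limit)")
        if self.rho <= _GIG_BOUNDARY and self.lam >= 0:
            raise ValueError("GIG with rho=0 requires lam < 0 (inverse-gamma limit)")


@dataclass(frozen=True)
class StudentTParams:
    """Multivariate Student-t parameters (df, location, scale matrix)."""

    df: float
    loc: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("Student-t df must be positive")
        loc = np.atleast_1d(np.asarray(self.loc, dtype=float))
        scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        if scale.shape[0] != scale.shape[1] or scale.shape[0] != loc.shape[0]:
            raise ValueError("scale must be square and conform with loc")
        object.__setattr__(self, "loc", loc)
        object.__setattr__(self, "scale", scale)


def sample_inverse_gaussian(mu, lam_shape, rng: np.random.Generator):
    """Draw from the inverse-Gaussian law with mean ``mu`` and shape ``lam_shape``.

    Vectorized Michael-Schucany-Haas construction: with w = mu*y/lam for a
    squared standard normal y, the smaller root of the defining quadratic is
    mu * 2/(2 + w + sqrt(w(w+4))) (conjugate form, stable for huge w) and is
    accepted with probability mu/(mu + x).
    """
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam_shape, dtype=float)
    if np.any(mu <= 0) or np.any(lam <= 0) or not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lam))):
        raise ValueError("inverse-Gaussian parameters must be finite and positive")
    mu, lam = np.broadcast_arrays(mu, lam)
    shape = mu.shape
    y = rng.standard_normal(shape) ** 2
    with np.errstate(over="ignore", invalid="ignore"):
        w = mu * y / lam
        z = 2.0 / (2.0 + w + np.sqrt(w * (w + 4.0)))
        # asymptotic branch avoids overflow of w*(w+4)
        big = w > 1e100
        if np.any(big):
            z = np.where(big, 1.0 / w, z)
        x = mu * z
        u = rng.random(shape)
        accept_small = u < 1.0 / (1.0 + z)
        out = np.where(accept_small, x, mu / np.maximum(z, 1e-300))
    out = np.clip(out, 1e-300, 1e300)
    if out.ndim == 0:
        return float(out)
    return out


def sample_gig(params: GIGParams, rng: np.random.Generator, size=None):
    """Draw from giG(lam, rho, chi) with density ∝ x^(lam-1) exp{-(rho·x+chi/x)/2}.

    Reduces to scipy's two-parameter ``geninvgauss(p, b)`` via the scaling
    ``x = sqrt(chi/rho)·z`` with ``b = sqrt(rho·chi)``; the gamma and
    inverse-gamma boundary cases are handled explicitly.
    """
    lam, rho, chi = params.lam, params.rho, params.chi
    if chi <= _GIG_BOUNDARY:
        # gamma(lam, rate=rho/2) limit
        return rng.gamma(shape=lam, scale=2.0 / rho, size=size)
    if rho <= _GIG_BOUNDARY:
        # inverse-gamma(-lam, chi/2) limit
        return (chi / 2.0) / rng.gamma(shape=-lam, scale=1.0, size=size)
    b = np.sqrt(rho * chi)
    z = stats.geninvgauss.rvs(lam, b, random_state=rng, size=size)
    return np.sqrt(chi / rho) * z


def sample_gig_vector(lam: float, chi, rng: np.random.Generator, rho: float = 1.0):
    """Vector of giG(lam, rho, chi_i) draws for an array of chi values.

    Half-integer orders use the closed inverse-Gaussian reduction
    giG(-1/2, rho, chi) = iG(sqrt(chi/rho), chi) (and the reciprocal identity
    for +1/2), fully vectorized; other orders fall back to scipy's
    scalar-parameter generator per element.
    """
    chi = np.asarray(chi, dtype=float)
    chi_f = np.maximum(chi, 1e-280)
    if lam == -0.5:
        return sample_inverse_gaussian(np.sqrt(chi_f / rho), chi_f, rng)
    if lam == 0.5:
        # 1/X ~ giG(-1/2, chi, rho) when X ~ giG(1/2, rho, chi)
        inv = sample_inverse_gaussian(np.sqrt(rho / chi_f), np.full_like(chi_f, rho), rng)
        return 1.0 / np.maximum(inv, 1e-300)
    out = np.empty_like(chi_f)
    flat = chi_f.ravel()
    res = np.empty_like(flat)
    for i, c in enumerate(flat):
        res[i] = sample_gig(GIGParams(lam, rho, float(c)), rng)
    out[...] = res.reshape(chi_f.shape)
    return out


def gig_logpdf(x, params: GIGParams):
    """Normalized log-density of giG(lam, rho, chi) (boundary cases via limits)."""
    lam, rho, chi = params.lam, params.rho, params.chi
    x = np.asarray(x, dtype=float)
    if chi <= _GIG_BOUNDARY:
        return stats.gamma.logpdf(x, a=lam, scale=2.0 / rho)
    if rho <= _GIG_BOUNDARY:
        return stats.invgamma.logpdf(x, a=-lam, scale=chi / 2.0)
    b = np.sqrt(rho * chi)
    s = np.sqrt(chi / rho)
    return stats.geninvgauss.logpdf(x / s, lam, b) - np.log(s)


def sample_inverse_wishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw an SPD matrix from IW(df, scale); mean is scale/(df-d-1) for df > d+1.

    Bartlett decomposition: with W ~ Wishart(df, scale^{-1}) built from a
    lower-triangular factor of chi and normal variates, the draw is W^{-1}.
    """
    scale = np.atleast_2d(np.asarray(scale, dtype=float))
    d = scale.shape[0]
    if df <= d - 1:
        raise ValueError(f"inverse-Wishart df must exceed d-1={d - 1}")
    try:
        L_scale = np.linalg.cholesky(scale)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("inverse-Wishart scale matrix is not SPD") from exc
    # Bartlett factor of Wishart(df, I)
    A = np.zeros((d, d))
    idx = np.tril_indices(d, k=-1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(d)] = np.sqrt(rng.chisquare(df - np.arange(d)))
    # W = L_inv_scale A A^T L_inv_scale^T with L_inv_scale = chol(scale^{-1}) = L_scale^{-T};
    # the inverse-Wishart draw is W^{-1} = L_scale A^{-T} A^{-1} L_scale^{T}.
    Ainv = solve_triangular(A, np.eye(d), lower=True)
    M = L_scale @ Ainv.T
    return M @ M.T


def logpdf_mvt(x: np.ndarray, params: StudentTParams) -> float:
    """Multivariate Student-t log-density at ``x``.

    log Γ((ν+d)/2) − log Γ(ν/2) − (d/2)log(νπ) − ½log|S|
    − ((ν+d)/2) log{1 + (x−m)ᵀS⁻¹(x−m)/ν}.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    d = params.loc.shape[0]
    df = params.df
    try:
        L = np.linalg.cholesky(params.scale)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("Student-t scale matrix is not SPD") from exc
    dev = np.linalg.solve(L, x - params.loc)
    quad = float(dev @ dev)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(
        special.gammaln((df + d) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * d * np.log(df * np.pi)
        - 0.5 * logdet
        - 0.5 * (df + d) * np.log1p(quad / df)
    )


def log_multigamma(p: int, x: float) -> float:
    """Log multivariate gamma log Γ_p(x); requires x > (p−1)/2."""
    if x <= (p - 1) / 2.0:
        raise ValueError(f"log_multigamma requires x > (p-1)/2 = {(p - 1) / 2.0}")
    return float(special.multigammaln(x, p))
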
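"""Synthetic-data generators for the three benchmark clustering scenarios.

Scenario ``lamb`` draws data from the latent factor mixture itself (shared
sparse loadings, Gaussian mixture on d0-dimensional factors); ``mfa`` is a
mixture of sparse factor analyzers with cluster-specific loadings and
observed-space intercepts; ``spcount`` produces log-transformed zero-inflated
sparse Poisson counts mimicking single-cell expression data.  Cluster
weights follow the main/minor scheme: the first floor(2 k0/3) "main"
clusters share a common weight and the remaining minor clusters together
weigh as much as a single main cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "cluster_weights",
    "cluster_weight_fractions",
    "generate_lamb",
    "generate_mfa",
    "generate_spcount",
    "generate",
    "desk_preset",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; defaults follow the benchmark grid (n=2000, p=1000).

    ``separation`` scales the spread of cluster means (latent-space for
    lamb, observed-space intercepts for mfa, log-rate shifts for spcount);
    ``sparsity`` is the fraction of exactly-zero loadings (lamb/mfa) or of
    differentially-shifted genes (spcount); ``zero_inflation`` applies to
    spcount only.
    """

    scenario: str = "lamb"
    n: int = 2000
    p: int = 1000
    k0: int = 10
    d0: int = 20
    separation: float = 3.0
    sparsity: float = 0.3
    noise_sd: float = 1.0
    zero_inflation: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in {"lamb", "mfa", "spcount"}:
            raise ValueError("scenario must be one of lamb, mfa, spcount")
        if self.k0 < 2:
            raise ValueError("k0 must be >= 2")
        if self.d0 >= self.n:
            raise ValueError("true latent dimension d0 must be < n")
        for name in ("sparsity", "zero_inflation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def desk_preset(scenario: str = "lamb", seed: int | None = None, **overrides) -> ScenarioConfig:
    """Reduced preset (n=300, p=500, k0=5) for quick runs and CI."""
    base = dict(scenario=scenario, n=300, p=500, k0=5, seed=seed)
    base.update(overrides)
    return ScenarioConfig(**base)


@dataclass
class SyntheticDataset:
    """Generated matrix plus the ground truth that produced it."""

    Y: np.ndarray
    true_labels: np.ndarray
    weights: np.ndarray
    config: ScenarioConfig
    true_eta: np.ndarray | None = None
    true_Lambda: np.ndarray | None = None


def cluster_weight_fractions(k0: int) -> list[Fraction]:
    """Exact rational main/minor cluster weights.

    m = floor(2 k0 / 3) main clusters with weight 1/(m+1) each; the k0 - m
    minor clusters share a single main weight equally.
    """
    if k0 < 2:
        raise ValueError("k0 must be >= 2")
    m = (2 * k0) // 3
    n_minor = k0 - m
    if m < 1 or n_minor < 1:
        raise ValueError(f"k0={k0} leaves no main or no minor clusters")
    main = Fraction(1, m + 1)
    minor = main / n_minor
    weights = [main] * m + [minor] * n_minor
    assert sum(weights) == 1
    return weights


def cluster_weights(k0: int) -> np.ndarray:
    """Main/minor cluster weights as floats (exact rational construction)."""
    return np.array([float(w) for w in cluster_weight_fractions(k0)])


def _draw_labels(cfg: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    w = cluster_weights(cfg.k0)
    labels = rng.choice(cfg.k0, size=cfg.n, p=w)
    return labels, w


def _sparse_loadings(p: int, d: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    Lam = rng.standard_normal((p, d))
    Lam[rng.random((p, d)) < sparsity] = 0.0
    return Lam


def generate_lamb(cfg: ScenarioConfig) -> SyntheticDataset:
    """Latent factor mixture: y_i = Lambda0 eta_i + eps_i, eta_i ~ N(mu_{c_i}, I).

    Cluster means mu_h ~ N(0, separation^2 I_{d0}); residual variances
    sigma_j^2 ~ U(0.5, 1.5) * noise_sd^2.
    """
    rng = np.random.default_rng(cfg.seed)
    labels, w = _draw_labels(cfg, rng)
    Lam = _sparse_loadings(cfg.p, cfg.d0, cfg.sparsity, rng)
    mu = cfg.separation * rng.standard_normal((cfg.k0, cfg.d0))
    eta = mu[labels] + rng.standard_normal((cfg.n, cfg.d0))
    sigma2 = cfg.noise_sd**2 * rng.uniform(0.5, 1.5, size=cfg.p)
    Y = eta @ Lam.T + rng.standard_normal((cfg.n, cfg.p)) * np.sqrt(sigma2)[None, :]
    return SyntheticDataset(Y=Y, true_labels=labels, weights=w, config=cfg, true_eta=eta, true_Lambda=Lam)


def generate_mfa(cfg: ScenarioConfig) -> SyntheticDataset:
    """Mixture of sparse factor analyzers: cluster-specific loadings and intercepts.

    y_i = mu_{c_i} + Lambda_{c_i} eta_i + eps_i with eta_i ~ N(0, I_{d0});
    intercept entries are N(0, separation^2 / 4) so cluster separation lives
    in the observed space.
    """
    rng = np.random.default_rng(cfg.seed)
    labels, w = _draw_labels(cfg, rng)
    Lams = np.stack([_sparse_loadings(cfg.p, cfg.d0, cfg.sparsity, rng) for _ in range(cfg.k0)])
    mus = (cfg.separation / 2.0) * rng.standard_normal((cfg.k0, cfg.p))
    eta = rng.standard_normal((cfg.n, cfg.d0))
    Y = mus[labels] + np.einsum("npd,nd->np", Lams[labels], eta)
    Y += cfg.noise_sd * rng.standard_normal((cfg.n, cfg.p))
    return SyntheticDataset(Y=Y, true_labels=labels, weights=w, config=cfg, true_eta=eta)


def generate_spcount(cfg: ScenarioConfig) -> SyntheticDataset:
    """Log-transformed zero-inflated sparse Poisson counts.

    Genes carry a shared baseline log-rate; in each cluster a sparse random
    subset (fraction ``sparsity``) of genes is shifted by ±separation on the
    log scale.  Counts are Poisson, independently zeroed with probability
    ``zero_inflation``; the output is log(1 + count).
    """
    rng = np.random.default_rng(cfg.seed)
    labels, w = _draw_labels(cfg, rng)
    base_log = rng.normal(0.0, 1.0, size=cfg.p)
    shifts = np.zeros((cfg.k0, cfg.p))
    for h in range(cfg.k0):
        mask = rng.random(cfg.p) < cfg.sparsity
        shifts[h, mask] = cfg.separation * rng.choice([-1.0, 1.0], size=int(mask.sum()))
    rates = np.exp(base_log[None, :] + shifts[labels])
    counts = rng.poisson(rates).astype(float)
    counts[rng.random(counts.shape) < cfg.zero_inflation] = 0.0
    Y = np.log1p(counts)
    return SyntheticDataset(Y=Y, true_labels=labels, weights=w, config=cfg)


_GENERATORS = {"lamb": generate_lamb, "mfa": generate_mfa, "spcount": generate_spcount}


def generate(cfg: ScenarioConfig) -> SyntheticDataset:
    """Dispatch on ``cfg.scenario``."""
    return _GENERATORS[cfg.scenario](cfg)
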
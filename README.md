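# lambclust

Bayesian model-based clustering of high-dimensional data (bulk and
single-cell transcriptomics being the motivating case: cells × genes with
p ≫ n) has a structural failure mode: as the number of variables p grows
with the sample size fixed, the exact posterior over partitions can
collapse onto a trivial answer — every observation in one cluster, or every
observation in its own cluster — regardless of any real group structure in
the data. `lambclust` provides

1. a **latent mixture for Bayesian clustering**: a Dirichlet-process
   Gaussian mixture placed on low-dimensional latent factors under a sparse
   factor measurement model, which escapes the collapse by clustering in a
   d-dimensional latent space that the p observed variables inform ever more
   strongly as p grows; and
2. a **degeneracy lab** that computes the collapse numerically — exact
   marginal likelihoods, exhaustive partition posteriors for small n, the
   merge-ratio statistic driving the limits, and the Bayes-oracle partition
   posterior that the latent model approaches as p → ∞.

## Model

Observed data `y_i ∈ R^p` are noisy linear measurements of latent factors
`η_i ∈ R^d` (d ≪ p), and the mixture lives at the latent level:

    y_i | η_i  ~  N_p(Λ η_i, Σ),        Σ = diag(σ_1², …, σ_p²)
    η_i        ~  Σ_h π_h N_d(μ_h, Δ_h)

with a Dirichlet process prior on the weights (concentration α ~ Ga(a_α, b_α)),
a normal–inverse-Wishart base measure NIW(0, κ₀, ν₀, ξ²I_d) on (μ_h, Δ_h),
a Dirichlet–Laplace shrinkage prior DL(a) on vec(Λ), and inverse-gamma
priors on the residual variances. The latent dimension d is set empirically
as the smallest number of singular values of the centered data explaining
95% of the variance.

Posterior computation is a collapsed Gibbs sampler — cluster means are
integrated out analytically and cluster labels follow the
Chinese-restaurant-process conditional with normal–inverse-Wishart
posterior-predictive (Student-t) weights — interleaved with Jain–Neal
split-merge Metropolis–Hastings moves built from restricted Gibbs scans.
Partitions are summarized by the posterior similarity matrix, the
Binder-loss point estimate over visited partitions, the posterior of the
cluster count k_n, and adjusted-Rand-index credible intervals.

## Worked example

Simulate a latent factor mixture (3 clusters, d₀ = 5, separation 4), fit,
and summarize:

```python
import numpy as np
import lambclust as lc

ds = lc.generate(lc.ScenarioConfig(scenario="lamb", n=120, p=80, k0=3,
                                   d0=5, separation=4.0, seed=7))
res = lc.fit(lc.DataMatrix(ds.Y),
             cfg=lc.FitConfig(n_iter=600, burn_in=200, thin=4, seed=7))
draws = lc.PartitionDraws(res.draws, res.iteration_index)
labels = lc.binder_point_estimate(draws)
values, probs = lc.posterior_cluster_count(draws)
print("d_hat:", res.d_hat)
print("Binder-estimate clusters:", len(np.unique(labels)))
print("ARI vs truth:", round(lc.adjusted_rand_index(labels, ds.true_labels), 3))
print("P(kn = k):", dict(zip(values.tolist(), np.round(probs, 3).tolist())))
```

prints

```
d_hat: 4
Binder-estimate clusters: 3
ARI vs truth: 1.0
P(kn = k): {3: 1.0}
```

The empirical-Bayes rule picked d̂ = 4 latent dimensions (the three cluster
means plus within-cluster spread span fewer effective directions than
d₀ = 5 at this separation), the Binder point estimate recovers the three
true clusters exactly (adjusted Rand index 1.0), and the posterior puts all
its mass on k_n = 3.

The same workflow from the shell:

```
$ lambclust simulate --scenario lamb --n 120 --p 80 --k0 3 --d0 5 \
      --separation 4 --seed 7 --output-dir sim
wrote lamb dataset (n=120, p=80, k0=3) to sim
$ lambclust fit --input sim/Y.csv --iters 600 --burnin 200 --thin 4 \
      --seed 7 --output-dir fit_out
d_hat=4  clusters=3  outputs in fit_out
$ lambclust summarize --draws fit_out/draws.csv \
      --reference sim/true_labels.csv --output-dir summary
binder estimate: 3 clusters; ARI 95% credible interval [0.975, 1.000]
```

`lambclust fit` writes the point-estimate labels, the posterior similarity
matrix, the k_n distribution, traces, the retained label draws, and a JSON
manifest from which the run can be reproduced exactly
(`lambclust fit --manifest fit_out/manifest.json`). `lambclust degeneracy`
tabulates the posterior-collapse grid described below.

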
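# Methods

## Model

`lambclust` clusters n observations of dimension p through a latent factor
mixture: conditionally on d-dimensional latent factors η_i, the data are
Gaussian measurements y_i ~ N_p(Λη_i, Σ) with diagonal residual covariance
Σ = diag(σ_1², …, σ_p²); the η_i follow a Dirichlet-process mixture of
d-variate Gaussians. The cluster-specific parameters live entirely at the
latent level, so the effective parameter count grows with d, not p, and the
observed variables act as p repeated noisy measurements of each η_i — the
information about the latent position accumulates as p grows, which is what
lets the partition posterior escape the high-dimensional collapse exhibited
by observed-space Gaussian mixtures (see "Degeneracy lab" below).

Priors:

* **Loadings.** vec(Λ) ~ DL(a), the Dirichlet–Laplace global–local
  shrinkage prior: λ_jh | ψ, φ, τ ~ N(0, ψ_jh φ_jh² τ²) with local scales
  ψ_jh ~ Exp(1/2), a Dirichlet(a, …, a) allocation φ over all p·d entries,
  and a global scale τ ~ Ga(p·d·a, 1/2). Default a = 0.5.
* **Mixture.** Weights from a Dirichlet process with concentration
  α ~ Ga(a_α, b_α) (defaults 0.1, 0.1), handled throughout by the
  Chinese-restaurant marginal — stick-breaking weights are never
  instantiated. Base measure NIW(μ₀ = 0, κ₀, ν₀, ξ²I_d) on (μ_h, Δ_h);
  defaults ξ² = 20, κ₀ = 0.001, ν₀ = d + 50. Cluster means μ_h are always
  integrated out analytically; only the Δ_h are kept in the state.
* **Residuals.** σ_j⁻² ~ Ga(a_σ, b_σ), defaults (1, 0.3).

The latent dimension d is chosen empirically: the smallest d whose leading
singular values of the column-centered data explain at least 95% of the
total variance (full SVD when min(n, p) ≤ 200, implicitly restarted Lanczos
otherwise; the variance denominator is the full squared Frobenius norm, so
truncation does not bias the ratios). Variability is measured on centered
data — the model has no intercept — and a flag disables centering. The
singular triplets initialize Λ and η with the scaling Λ₀ = V_d diag(s)/√n,
η₀ = √n U_d (so η₀ᵀη₀ = nI, matching the conditioning regime of the
loadings update), and k-means on η₀ initializes the labels with k chosen by
maximum average silhouette width over 2…min(20, n−1).

## Sampler

One sweep executes, in order:

1. **Loadings.** Each row λ_j from its Gaussian conditional with precision
   D_j⁻¹ + σ_j⁻² ηᵀη, D_j = τ² diag(ψ_j1 φ_j1², …); all p rows in one
   batched Cholesky pass.
2. **Cluster covariances.** Δ_h ~ IW(ν₀ + n_h, ξ²I + Σ_{i∈h}(η_i − η̄_h)(…)ᵀ
   + (κ₀n_h/(κ₀+n_h)) η̄_h η̄_hᵀ) for every occupied cluster.
3. **Latent factors**, sequentially. With the cluster mean integrated out,
   the prior of η_i given the other members of its cluster is
   N(μ̂_{h,−i}, (1 + 1/κ̂_{h,−i}) Δ_h), κ̂ = κ₀ + n_{h,−i},
   μ̂ = n_{h,−i} η̄_{h,−i}/κ̂; combining with the likelihood of y_i gives a
   Gaussian with precision ΛᵀΣ⁻¹Λ + (κ̂/(κ̂+1)) Δ_h⁻¹. This is the exact
   location-marginalized full conditional. The superficially natural
   alternative — drawing μ_h from its conditional given the *other* members
   only and then η_i given (μ_h, y_i) — has covariance
   Ω + Ω(κ̂Δ_h)⁻¹Ω with Ω = (ΛᵀΣ⁻¹Λ + Δ_h⁻¹)⁻¹ and is *not* the
   conditional (it ignores the information y_i carries about μ_h; in the
   scalar benchmark ΛᵀΣ⁻¹Λ = Δ = κ̂ = 1 it gives variance 3/4 where the
   conditional has 2/3). The package implements the exact form.
4. **Labels**, a sequential collapsed CRP scan: c_i is drawn over occupied
   clusters with weight n_{h,−i} times the NIW posterior-predictive
   Student-t density of η_i (df ν_n − d + 1, location s/κ_n, scale
   Ψ_n(κ_n+1)/(κ_n(ν_n−d+1)) with Ψ_n = ξ²I + Σηηᵀ − ssᵀ/κ_n), plus a new
   cluster with weight α times the prior predictive. Weights are normalized
   in log space through the running maximum; raw-space normalization is
   never used, so allocations remain exact for p up to 10⁴ and beyond.
   Emptied clusters are deleted and labels compacted. Clusters opened
   during the scan receive Δ_h from their step-2 conditional at scan end;
   since Δ is refreshed in step 2 before anything conditions on it again,
   this partially collapsed ordering leaves the chain's law unchanged.
5. **Concentration.** The Escobar–West auxiliary update: φ ~ Beta(α+1, n),
   then α from the two-component gamma mixture with shapes a_α + r and
   a_α + r − 1 (r = occupied clusters) and rate b_α − log φ.
6. **Residual variances.** σ_j⁻² ~ Ga(a_σ + n/2, b_σ + SSR_j/2).
7. **Shrinkage scales**, as one exact block draw from
   p(φ, τ, ψ | Λ) = p(φ|Λ) p(τ|φ,Λ) p(ψ|φ,τ,Λ), executed in that order:
   T_jh ~ giG(a−1, 1, 2|λ_jh|) with φ = T/ΣT; τ ~ giG(pd(a−1), 1,
   2Σ|λ_jh|/φ_jh) — note the *negative* order parameter pd(a−1), which is
   what the Dirichlet–Laplace conjugacy yields and what the
   joint-distribution test confirms; then 1/ψ_jh ~ iG(τφ_jh/|λ_jh|, 1).
   |λ_jh| is floored at 1e−300 before forming iG/giG parameters.

After the scan, with probability 0.5 (configurable) the sweep appends one
Jain–Neal split-merge attempt: two anchors drawn uniformly; co-clustered
anchors trigger a split grown from a uniform random launch state by
n_restricted_scans restricted Gibbs scans (default 5) whose final scan is
the proposal, otherwise the merge is proposed with the reverse-path scan
probability evaluated by forcing a launch-plus-scan trajectory through the
current configuration. The acceptance ratio combines the DP EPPF factor at
the current α, marginal NIW likelihoods of the affected blocks, and the
scan probability, entirely in log space. The split-merge move supplements
(never replaces) the full label scan.

Defaults for a run: 6000 sweeps, 1000 burn-in, thinning 5 (1000 retained
label vectors), column-centering on. All defaults are configurable through
`Hyperparams` and `FitConfig`.

### Numerical choices

* Inverse-Gaussian draws use the Michael–Schucany–Haas construction with
  the conjugate-root form x = μ·2/(2 + w + √(w(w+4))), stable for huge w;
  results are clipped to [1e−300, 1e300].
* GIG draws at half-integer order (the a = 0.5 default puts every array-
  valued GIG at order ±1/2) use the exact inverse-Gaussian reduction,
  vectorized; other orders fall back to scipy's generator.
* Inverse-Wishart draws use the Bartlett decomposition.
* SPD factorizations that fail get one retry with 1e−10 jitter on the
  diagonal.
* The sequential label scan and the restricted scans are numba nopython
  kernels that consume the caller's `numpy.random.Generator`, so runs are
  exactly reproducible given the seed and identical to a pure-Python
  implementation in law.

## Partition summaries

The posterior similarity matrix P holds pairwise co-clustering frequencies
over retained draws. The point estimate is the *visited* partition
minimizing the posterior-expected equal-cost Binder loss
Σ_{i<j} |1{c_i=c_j} − P_ij| (ties broken by earliest iteration); no search
outside the visited set is attempted. The cluster-count posterior is the
empirical distribution of k_n over retained draws, and ARI credible
intervals are equal-tailed quantile intervals of the per-draw ARI against a
reference labeling.

## Degeneracy lab

For observed-space Gaussian mixtures the package computes exactly, in log
space: the marginal likelihood of a cluster under the conjugate NIW prior
(cluster-specific covariances), the marginal of the whole sample when all
clusters share one covariance, the DP exchangeable partition probability
function, the full posterior over all set partitions for n ≤ 12
(restricted-growth-string enumeration, log-sum-exp normalization), the
merge-ratio statistic (pre-merge over post-merge marginal likelihood), and
the Bayes-oracle partition posterior — the partition posterior computed on
the true latent factors under a location mixture with shared covariance,
N(0, Δ/κ₀) means, and the Jeffreys prior |Δ|^{−(d+1)/2}, whose marginal is
finite for n > d and is evaluated in closed form (the (ν₀ → 0, Λ₀ → 0)
limit of the shared-covariance marginal, with the partition-independent
constants dropped).

Determinants of Λ₀ + YᵀWY with diagonal Λ₀ and n < p go through the matrix
determinant lemma on the n × n Gram matrix, so the p-grid up to p = 1000
(and far beyond) costs the same as p = 10; the shared-covariance
enumeration additionally batches the n × n determinants over chunks of
20000 partitions.

Demonstration constants: the cluster-specific ("flexible") regime uses
ν₀ = p + 2, κ₀ = 1, Λ₀ = I_p and prior mean μ₀ = 1_p; the shared regime
uses ν₀ = 2p with μ₀ = 0. The ‖μ₀‖² = p choice matters: the flexible-
covariance collapse to one cluster requires the prior mean's norm to grow
at the data's scale (with μ₀ = 0 the merge of two balanced blocks stays
weakly disfavored at any affordable p, while singleton merges are strongly
favored), and the demonstrations use it for that reason. With these
settings, on n = 10 i.i.d. standard normal data, the posterior mass on the
single-cluster partition (flexible regime) and on the all-singletons
partition (shared regime) are both monotone along p ∈ {50, 200, 1000} and
exceed 0.99 at p = 1000.

## Synthetic data

Three generators emulate the benchmark scenarios; cluster labels always
follow the main/minor weight scheme: m = ⌊2k₀/3⌋ main clusters with weight
1/(m+1) each and the remaining k₀ − m minor clusters sharing one main
weight equally (k₀ = 25 gives 16 main clusters of weight 1/17 and 9 minor
clusters totaling 1/17; weights are built in exact rational arithmetic).

* **lamb** — the model's own structure: shared sparse loadings (entries
  zero with probability `sparsity`, else standard normal), cluster means
  μ_h ~ N(0, separation²I) in latent space, η_i ~ N(μ_{c_i}, I), residual
  variances σ_j² ~ U(0.5, 1.5)·noise_sd².
* **mfa** — a mixture of sparse factor analyzers: cluster-specific sparse
  loadings and observed-space intercepts with entries
  N(0, separation²/4), η_i ~ N(0, I); between-cluster covariance
  heterogeneity that the latent mixture mis-specifies.
* **spcount** — log-transformed zero-inflated sparse Poisson counts: a
  shared log-normal baseline rate per gene, a sparse random subset of genes
  shifted by ±separation on the log scale per cluster, Poisson counts
  independently zeroed with probability `zero_inflation`, output
  log(1 + count).

Default constants — sparsity 0.3, separation 3, noise_sd 1, zero_inflation
0.3, d₀ = 20, and the benchmark grid n = 2000, p ∈ {1000, 2500},
k₀ ∈ {10, 15, 25} — are fixed once in `ScenarioConfig`; a reduced "desk"
preset (n = 300, p = 500, k₀ = 5) serves interactive runs and CI. These
generators capture cluster structure, sparse loadings, discreteness and
zero inflation, but not library-size variation, batch effects, or
structured dropout; a pass on them shows the machinery recovers planted
structure under the model's assumptions (and mild violations), not that it
resolves every artifact of real single-cell data.

## Validation design

* Every conjugate full conditional is checked against an independent route:
  exact small-case algebra, numerical quadrature at p (or d) = 1 within
  1e−5–1e−6, Monte-Carlo integration at dimension 2 within four standard
  errors, and Monte-Carlo moments at fixed conditioning states.
* Joint-distribution correctness uses two complementary harnesses. A
  fresh-prior-draw harness applies a single update to an exact prior draw
  with resimulated data and compares monitor means against pure prior draws
  (i.i.d., full power per iteration, run at the default hyperparameters).
  The full-sampler test runs replicated successive-conditional chains
  (4000 replicates × 10 sweeps at n = 20, p = 10, d = 2): started from
  exact prior draws, the final states are again exact prior draws under a
  correct sampler and independent across replicates. A single long chain is
  deliberately avoided: under informative resimulated data the shrinkage
  hierarchy's autocorrelation time exceeds any affordable chain length, so
  time-average standard errors cannot be estimated honestly. The replicated
  test runs at hyperparameters under which the chain moves
  (ξ² = 2, κ₀ = 1, ν₀ = d + 4, a_α = b_α = 1, a_σ = 2, b_σ = 1); the
  conditionals are the same code paths at any setting, and the
  default-hyperparameter single-update harness covers the defaults.
* The label scan and split-merge are validated against exhaustively
  enumerated partition posteriors on n = 6, d = 1 conjugate toys
  (total-variation distance, 1.2·10⁵ retained draws for the combined
  chain), separately for the Gibbs-only, split-merge-only, and combined
  chains.
* End-to-end recovery uses the desk preset with 1500 sweeps (500 burn-in,
  thin 5) across five seeds, requiring Binder-estimate ARI ≥ 0.9 against
  the truth in every seed; the growing-dimension experiment fixes n = 120,
  d₀ = 10 and checks that the median per-entry RMSE of the fitted Λη
  against the true signal is nonincreasing along p ∈ {100, 400, 1600} with
  300-sweep chains. Problem sizes throughout the suite are desk-scale
  choices: large enough for the checked property to hold with margin,
  small enough to run routinely.

## Known limitations

* d is fixed by the empirical-Bayes rule; no posterior inference on d.
* Only the Dirichlet–Laplace prior on Λ and the DP partition prior are
  implemented (no horseshoe, Pitman–Yor, or mixture-of-finite-mixtures
  variants).
* The Gaussian measurement model is assumed; count data enter through a
  log(1 + x) transform rather than a native likelihood.
* Exhaustive partition enumeration is capped at n = 12 (Bell(12) ≈ 4.2M).
* Single-process execution; no distributed or variational approximations.
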
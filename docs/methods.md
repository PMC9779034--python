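# Methods

`arealrisk` implements a small-area ecological analysis of areal event
counts — the concrete motivating case is the risk of physical
intimate-partner violence against women measured per administrative
department — in three stages: indirect standardization (SMR), Bayesian
exploratory factor analysis (BEFA) of area-level covariates, and the
Besag–York–Mollié (BYM) spatial convolution model. A synthetic-data
generator reproduces the statistical anatomy of such a study so that
every stage is testable without access to restricted registry and
survey data.

## Standardized morbidity ratios

With observed counts `y_i` and populations at risk `n_i` over `m`
areas, expected counts use a single all-areas reference rate:

    e_i = n_i * (Σ y / Σ n),        SMR_i = y_i / e_i.

By construction `Σ e = Σ y`, so the population-weighted mean SMR is 1.
No age stratification is applied — the package accepts externally
computed `e_i` for users who have stratified expectations. The SMR is
an unstable quantity in small areas (its variance scales as `1/e_i`),
which is the motivation for the hierarchical model below.

The correlation screen (`correlation_matrix`) is a plain Pearson
product-moment matrix over covariate columns (Spearman by flag), used
to eyeball candidate groupings before the factor analysis.

## Bayesian exploratory factor analysis with dedicated loadings

Covariates are standardized columnwise (mean 0, sample SD 1). Each
variable `x_j` loads on *at most one* of `K_max` orthogonal latent
factors:

    x_ij = λ_j f_{i, z_j} + ε_ij,    ε_ij ~ N(0, σ_j²),   f_ik ~ N(0,1),

with allocation `z_j ∈ {0, 1, …, K_max}` and `z_j = 0` meaning no
factor structure. The number of active factors, the assignment of
variables to factors, the loadings, scores and idiosyncratic variances
are inferred jointly.

Priors and defaults:

* `λ_j ~ N(0, s0²)` with `s0 = 1` (loadings of standardized variables
  are bounded near 1 in magnitude, so unit scale is weakly
  informative).
* `σ_j² ~ InvGamma(2, 1)` (prior mean 1, matching standardized data).
* Allocation prior: unnormalized weight 1 on the null category and
  `conc / K_max` on each factor, default `conc = 0.2`, i.e. a variable
  is structured a priori with probability `conc/(1+conc) ≈ 0.17`. This
  sparsity default is deliberate: with a uniform allocation prior a
  variable is a priori 75% likely (at `K_max = 3`) to carry structure,
  and at moderate sample sizes the posterior then chases chance sample
  correlations (|r| ≈ 2/√m under independence). The parsimony prior
  makes the model a genuine dimension-selection device; it was
  validated on independently generated noise datasets and leaves
  strong structure (|λ| ≈ 0.8–0.9) untouched. Fully configurable.
* `min_dedicated = 2`: an active factor must own at least two
  variables; a one-variable factor is unidentifiable against the null
  because `λ` and `σ²` trade off freely. A stricter value of 3 is
  available.

Sampling is Metropolis-within-Gibbs:

1. Per-variable MH on `z_j` with the loading integrated out
   analytically (`x_j | f, z_j=k` is `N(0, σ_j² I + s0² f_k f_k')`,
   evaluated by rank-one determinant and Sherman–Morrison identities;
   this closed form is unit-tested against numerical quadrature).
   Moves that would leave a factor with 1..`min_dedicated`−1 members
   are excluded from the proposal set, with the asymmetry of the
   allowed sets corrected in the acceptance ratio.
2. Pair birth/death moves. Single-variable moves can never take a
   factor through occupancy 1, so an empty factor could never activate
   without them: a birth draws `min_dedicated` null variables uniformly
   and seeds a uniformly chosen empty factor; a death dissolves a
   minimally occupied factor. Both carry exact proposal-probability
   corrections (combinatorial counts forward and reverse), and several
   attempts are made per sweep.
3. Conjugate Gibbs updates of loadings, scores (factors are
   conditionally independent given the dedicated structure) and
   idiosyncratic variances.
4. Sign convention: for each active factor, the lowest-index dedicated
   variable loads positively; `(λ, f)` pairs are flipped accordingly in
   every stored draw. This pins the reflection invariance but not the
   factor *labels*; consumers should compare partitions, not raw
   indices, and the test suite does so.

Retention follows a posterior rule: a variable is retained when
`P(z_j = 0) < 0.5` (threshold configurable). The raw per-variable MH
acceptance rate is also reported, since low acceptance of allocation
moves is itself a useful diagnostic of a variable with no stable
factorial home. Factor scores passed downstream are posterior means,
re-standardized per column.

Not modeled: factor correlations (fixed orthogonal), cross-loadings,
ordinal measurement. These are limitations, not options.

## The BYM convolution model

    y_i | θ_i ~ Poisson(e_i θ_i),
    log θ_i  = α0 + x_i'β + u_i + v_i,

with `u` an intrinsic CAR (ICAR) field on the contiguity graph and `v`
iid heterogeneity. Contiguity is queen by default — two areas are
neighbours if their boundaries share at least one point — with rook
available. The ICAR prior has density

    p(u | τ_u) ∝ τ_u^{rank(Q0)/2} exp(−τ_u/2 · u'Q0u),   Q0 = D − W,

made proper by the per-component sum-to-zero constraint; each area's
conditional prior mean is its neighbours' average with precision
`τ_u·degree`. Areas with no neighbour (islands) have `u_i ≡ 0` and are
informed by covariates and `v` alone; the alternative of manually
adding an edge is available at the graph layer. `α0` and `β` carry
flat priors by default (a normal prior on each is available and is
required by the joint-distribution test below); `v_i ~ N(0, 1/τ_v)`;
`τ_u, τ_v ~ Gamma(0.5, 0.0005)`, the long-standing disease-mapping
convention for WinBUGS-era convolution models. A literal flat prior on
each `v_i` would make the model unidentifiable, which is why the
convolution reading with a Gaussian exchangeable `v` is used.

Covariates enter as plug-in posterior-mean factor scores (optionally
plus raw standardized columns); no uncertainty is propagated from the
factor stage — a deliberate two-stage design matching how such
analyses are run in practice.

### Sampler

Metropolis-within-Gibbs with these moves per sweep:

* a joint random-walk update of `(α0, β)`;
* ancillarity shifts trading a constant between one coefficient and
  `v` (the likelihood is untouched; this decouples coefficients from
  the heterogeneity field);
* confounding shifts trading `β_j` against the spatial field along the
  component-centered covariate direction (`β_j += t`, `u −= t·x̃_j`).
  Along that fixed direction the ICAR factor is Gaussian in `t`, so
  `t` is proposed from exactly that Gaussian and accepted on the
  Poisson remainder — near-independent sampling of the coordinate
  that is slow when a covariate is spatially smooth by chance;
* single-site updates of `u` proposed *inside* the sum-to-zero
  subspace: site `i` moves by `δ(1 − 1/n_c)` while every other member
  of its component moves by `−δ/n_c`. The constraint therefore holds
  exactly in every stored draw, and the kernel is exactly invariant
  for the constrained model under any intercept prior. (The classical
  alternative — update against the unconstrained CAR conditional, then
  recenter and fold the mean into the intercept — is only valid with a
  flat intercept prior and fails an exact joint-distribution test
  otherwise, which is why it was not used.) The Poisson part of the
  acceptance ratio uses running component sums, so a site update is
  O(1) with an O(component) vector update only on acceptance;
* vectorized independent random-walk updates of `v` (the full
  conditionals factorize over areas);
* multiplicative rescaling moves `u → cu` and `v → cv` with log-normal
  proposals and the `c^rank` Jacobian, evaluated with the
  corresponding precision integrated out analytically (the Gamma
  conditional is redrawn immediately afterwards, a standard
  partially-collapsed composition), so the field magnitudes — and
  hence the precisions — mix in single steps instead of creeping;
* a collapsed involutive regime swap
  `T(u, v) = (center(v), v − center(v) + u)`, which exchanges the two
  fields' shapes while keeping `u + v` (hence the likelihood) exactly
  fixed. `T` is linear and self-inverse, so its Jacobian has unit
  magnitude and plain MH applies. The convolution decomposition is
  only weakly identified, and without this move chains can lock for
  thousands of sweeps into a u-dominated or v-dominated explanation
  of the same totals; with the precisions marginalized the swap jumps
  between the regimes at marginal-prior cost;
* conjugate Gamma draws of `τ_u` (shape + rank(Q0)/2) and `τ_v`
  (shape + m/2).

Proposal scales adapt toward 20–40% acceptance during warm-up only, in
batches of 50 sweeps; the post-warm-up kernel is frozen, and an
attempt to adapt after freezing raises. Chains start from jittered
moment-based values. The default protocol is 10,000 iterations per
chain with the first 4,000 discarded as warm-up, 3 chains, no
thinning; every chain derives its stream from the user seed, so runs
are bit-reproducible.

Kernel correctness is tested two ways: a Geweke-style joint
distribution test (successive-conditional simulation alternating full
sweeps with data regeneration must preserve the prior marginals of
`τ_u`, `u'Q0u`, `α0`, `τ_v`; compared by KS against direct prior
simulation on a 4-node toy, with proper priors and heavy thinning —
two-sample KS is anti-conservative under autocorrelation, so the
successive chain is thinned ~30×), and a pure-prior check that Gibbs
sampling from the CAR full conditionals with recentering reproduces
the spectrally sampled constrained Gaussian.

## Synthetic studies

The generator emulates the study conditions the analysis assumes:

* **Graph**: 33 areas — a 5×6 queen grid plus two attached areas and
  one island — matching the scale of a national department map where
  one archipelago department has no land neighbour.
* **Populations**: log-normal around 50,000 women at risk (log-SD
  0.35); with the default base rate of 0.01 events per woman over the
  study window this yields ~500 expected cases per area.
* **Covariates**: 8 proportion-scale columns with means 58–98% and SDs
  3–10% (the scale of published departmental survey aggregates), of
  which six form two dedicated factors (loadings 0.8–0.9, mixed signs)
  and two are structure-free.
* **Risk surface**: `α0 = 0`, `β = (0.5, −0.3)` on the true factor
  scores, `σ_u = 0.3`, `σ_v = 0.1`; `u` drawn from the constrained
  ICAR by spectral decomposition (independent `N(0, σ_u²/λ_k)` weights
  on the positive-eigenvalue eigenvectors); counts Poisson.

All randomness flows from one integer seed through named CRC-keyed
substreams (scores, noise, u, v, y, populations, per-chain MCMC), so
adding a component never perturbs another's draws and every object is
bit-reproducible.

What the generator does **not** emulate: real boundary geometry, age
structure and stratified expectations, registry underreporting, survey
sampling error in the covariates, and spatial confounding between
covariates and the risk field (covariate scores are iid across areas).
Passing recovery tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to those features of
real data.

## Convergence diagnostics

Quantitative stand-ins for graphical convergence checks:

* **Split-chain R̂**: each chain is halved; with `M` half-chains of
  length `n`, `W = mean(s_m²)`, `B/n = var(x̄_m)`,
  `var⁺ = (n−1)/n·W + B/n`, `R̂ = √(var⁺/W)`. Requires ≥ 2 chains
  (`ChainSet.split()` covers the single-chain case explicitly).
* **ESS**: multi-chain autocorrelation sum `ρ̂_t = 1 − (W − mean_m
  ĉ_{t,m})/var⁺` with biased FFT autocovariances, truncated by
  Geyer's initial positive monotone pairs `Γ̂_k = ρ̂_{2k} + ρ̂_{2k+1}`;
  `ESS = CS/τ̂`, capped at the total draw count; constant chains
  report the cap with a zero-variance flag.

Both formulas are deliberately plain so that an independent
re-implementation reproduces them to numerical precision, and the test
suite holds them to 1e-8 against brute-force double-loop references.
The pipeline records pass/fail against configurable gates (R̂ < 1.05,
ESS > 400) in its MANIFEST; the gates report, they do not abort.
With the default protocol the coefficient chains clear the R̂ gate;
the precision chains (`τ_u`, `τ_v`) are the slowest-mixing quantities
and their ESS can sit below 400 — they are nuisance parameters here,
but longer runs are one config key away.

## Numerical and interface choices

* Eigenvalues below 1e-9 are treated as the ICAR null space.
* `e_iθ_i > 1e9` in the generator and `η > 700` in density evaluation
  are overflow guards (the latter returns −inf rather than raising).
* Posterior intervals are equal-tailed empirical quantiles with the
  sort-and-linearly-interpolate rule; exceedance `P(θ>1)` uses strict
  inequality.
* Quadrant classification of factor scores labels exact zeros on the
  positive side.
* Geometry predicates are exact on input coordinates; an optional
  epsilon buffer handles dirty exports. Contiguity from GeoJSON and
  from edge lists are interchangeable inputs everywhere.
* Degenerate inputs fail loudly and name the offender: constant
  covariate columns, zero total cases, non-positive populations,
  unknown or duplicate area ids, islands passed to the CAR full
  conditional.

## Problem sizes

Tests and the acceptance script run at the study's own scale: 33
areas, ~500 expected cases per area, the 10,000/4,000 protocol, 20
seeded replicates for coverage checks, m = 200 for factor-recovery
checks, and 20,000 draws for distributional comparisons. The full
suite completes in minutes on one core.

## Known limitations

* Two-stage plug-in scores: factor-analysis uncertainty does not
  propagate into coefficient intervals.
* Orthogonal factors only; no BYM2/Leroux reparameterization; no
  spatio-temporal extension (counts are pooled over the study window).
* The iid-covariate generator cannot exhibit spatial
  covariate-confounding, the hardest failure mode of real ecological
  regressions.
* `τ` chains mix slowest; their reported ESS is the honest number to
  watch when tightening inference on the random-effect variances.
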
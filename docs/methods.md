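# Methods

## The traits

All lengths are in µm, areas in µm², volumes in µm³; no unit autodetection
is attempted. The derived traits are geometric idealizations of
photographed structures:

- **Eye surface.** The visible compound eye is half of an ellipsoid of
  revolution. The sphere radius is read as the average of the eye width
  and half the eye height, `r = (w + h/2)/2`, and the area is `4πr²/2`.
  The phrase behind this convention admits a second reading — the average
  of the two semi-axes, `r = (w + h)/4` — so the rule is a configuration
  option (`eye_radius_rule`) and is echoed into every report. The default
  tends to run low against published eye areas but is internally
  consistent, which is what ratio analyses need.
- **Funiculus surface.** A full ovoid with radius `r = (l/2 + w/2)/2`,
  minus the circular base `π(w/2)²` where the segment meets the pedicel:
  `4πr² − π(w/2)²`. Algebraically this is `π((l+w)² − w²)/4`, which is
  positive for any positive length, so the geometry guard can only fire in
  the optional half-ellipsoid variant (`hemisphere=True`), where a very
  wide, short funiculus is rejected.
- **Sensillum density** of one antennal surface side divides the count by
  half the funiculus surface, since each side exposes half the ovoid.
- **Replicate aggregation** averages the raw linear measurements per
  species first and derives areas from the means. The alternative (mean of
  per-replicate areas) differs by a Jensen gap of order the squared
  measurement CV (~0.1% at CV 3%); the chosen rule matches the
  "average width" phrasing of field practice and is order-invariant.
- **Attraction index.** Two-choice trap counts are summarized as
  `(t − c)/(t + c)`, the standard symmetric preference index bounded in
  [−1, 1]; it is undefined (an error, not a NaN) when no flies were caught.

## Phylogenetic signal

Let `V` be the Brownian variance–covariance matrix of the rooted tree
(shared root-to-tip path lengths; the stem edge above the root carries no
contrast information and is excluded). For a trait `x` the Brownian
log-likelihood is profiled analytically:

    â  = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹x
    σ̂² = (x − â1)ᵀ V⁻¹ (x − â1) / n
    ℓ  = −(n/2)·ln(2πσ̂²) − ½·ln|V| − n/2

**Pagel's λ** multiplies the off-diagonal of `V` by λ ∈ [0, 1]. The ML
estimate maximizes the profiled likelihood over a 101-point grid followed
by bounded refinement in the bracketing interval (λ tolerance 1e-8, ties
broken toward smaller λ). Both hypothesis tests (λ = 0, λ = 1) are
boundary likelihood-ratio tests: the null value lies on the edge of the
parameter space, so the χ²₁ tail probability is halved (50:50 χ²₀/χ²₁
mixture). Estimation is ML rather than REML throughout — the profiled
likelihood is simpler, the λ estimate is the quantity of interest, and the
small downward bias in σ̂² does not affect λ̂ or the LR orderings.

**Blomberg's K** is

    K = (MSE0/MSE) / E_BM[MSE0/MSE],   E_BM = [tr(V) − n/(1ᵀV⁻¹1)]/(n−1)

with MSE0 the ordinary and MSE the V-weighted mean squared error around
the GLS mean. K is exactly 1 on a star tree for any trait, and its mean
over Brownian simulations on a fixed tree is 1 (the suite checks
[0.9, 1.1] over 500 draws). The significance test permutes trait values
across tips with a seeded generator; the statistic is the GLS MSE
(smaller = more signal) and the p-value uses the add-one estimator
`(1 + #{MSE* ≤ MSE_obs})/(n_perm + 1)` with a default of 999 permutations.
A seed is mandatory — there is no silent global-state fallback.

**PGLS** solves `y = Xβ + ε`, `ε ~ N(0, σ²·V(λ))`, by whitening through
the Cholesky factor of `V(λ)`. In `brownian` mode λ = 1; in `ml_lambda`
mode (the default for the binary-trait analyses, matching the behaviour of
the R packages commonly used for these regressions) λ is re-estimated from
the regression residual likelihood with the same grid-plus-refinement
optimizer. Standard errors use `σ̂² = RSS_gls/(n − p)` and two-sided
t-tests with `n − p` degrees of freedom. With an identity covariance the
result reproduces OLS to 1e-10, and the intercept-only fit equals the GLS
mean â. The implementation was cross-checked during development against
independent R implementations (`phytools::phylosig`, `nlme::gls` with
`corPagel`/`corBrownian`) and agrees to numerical precision.

Numerical choices: covariance solves go through Cholesky factorizations;
log-determinants are sums of log diagonal factors, never raw determinants;
a 1e-10 diagonal jitter is added only when a factorization fails, with a
logged warning; zero-length branches are permitted. Trait/tree label
matching is strict and case-sensitive — labels differing only by case are
an error, and any pruning is reported, never silent. A constant trait is a
degenerate flag in the likelihood machinery and a hard error for K.

## The synthetic study

The generators define the conditions under which the statistics are
exercised; their defaults describe a genus-scale study: 62 species (59
when mirroring the tree-analysis subset), 3–8 replicate specimens per
species (default 5), measurement CV 3%.

- **Trees** are pure-birth (Yule): exponential waiting times at rate
  `b·k`, uniform choice of the splitting lineage, ultrametric by
  construction, rescaled to unit root-to-tip depth so that σ² is
  interpretable across runs.
- **Continuous traits** are single draws from `N(root·1, σ²·V(λ))` via
  Cholesky factorization of the λ-transformed covariance.
- **Binary traits** threshold a latent Brownian trait at its
  (1 − prevalence) empirical quantile, giving the binary columns genuine
  phylogenetic signal that iid Bernoulli draws would lack.
- **Morphometric tables**: log body length evolves by Brownian motion
  (log-scale SD 0.30 at the unit-depth root-to-tip scale, roughly the
  3-fold body-size range seen across the genus); head width is
  proportional to body length (0.36); a latent allocation axis `z`
  (Brownian, SD 0.45) shifts log eye area by +z/2 and log funiculus area
  by −z/2 around an isometric (slope-2) size trend. The EF ratio is
  therefore `e^z` — several-fold variation, independent of size by
  construction. Linear measurements are back-solved through the exact
  inverses of the surface formulas at fixed aspect ratios (eye height =
  1.2 × width, funiculus length = 1.5 × width), then replicate noise is
  applied multiplicatively. Because size and the EF ratio both evolve on
  the same tree, the built-in independence check is a *phylogenetic*
  regression: the PGLS slope of log EF on log body covers zero at its
  nominal rate, whereas ordinary OLS intervals under-cover on
  tree-structured data — the familiar pseudoreplication effect, and the
  reason the package carries PGLS in the first place.
- **Disc data**: log disc (eye:antenna) ratios form a two-group mixture
  (defaults 1.3 and 2.6, within-group log-SD 0.12 — an olfactory-biased
  and a visually-biased cluster); adult EF ratios are linked through a
  bivariate-normal copula against the *standardized total* log disc ratio
  (group separation included), so the population log–log correlation
  equals `rho_adult` exactly rather than being inflated by the bimodality.

Every generator is a pure function of (parameters, seed): a master seed
plus a fixed per-generator offset feeds `numpy.random.default_rng`, so
outputs are byte-identical on repeat and adding a generator never perturbs
another's stream. What the generators do **not** emulate: measurement
error correlated across structures within a specimen, missing data,
extinction (no death process in the trees), non-Brownian trait evolution
(no Ornstein–Uhlenbeck pull), or discrete trait co-evolution; passing
tests therefore demonstrate estimator correctness and calibration under
the stated model, not robustness to those violations.

## Problem sizes and tolerances

The calibration suite runs at the scale of the emulated study: 59-tip
trees, 200 replicate traits for λ recovery (mean λ̂ within [0.95, 1.00];
the estimator is bounded above), 500 for K (mean within [0.9, 1.1]), 100
shuffled traits for the no-signal check (mean λ̂ < 0.1), 200 datasets for
the permutation-test size (rejection rate in [0.02, 0.09] at nominal 0.05,
199 permutations each), and 200 replicates for PGLS interval coverage
(≥ 90% for β₁ = 0.5 with residual λ = 0.8). Exact equivalences (star-tree
K = 1, identity-covariance PGLS = OLS, optimizer vs. 1001-point grid) are
asserted at 1e-10 or 1e-4 log-likelihood as appropriate.

## Pipeline conventions

Reports serialize floats at 6 significant digits with sorted keys, so a
rerun on identical inputs and seed is byte-identical; the provenance block
echoes the full configuration, every convention flag and the seed. The
three PGLS analyses are reported with raw p-values plus a clearly labelled
Holm-adjusted column. The species trait table's `ommatidia` column is
optional (no input format carries it by default) and is NaN when absent.
The disc-vs-adult correlation is computed on log ratios, consistent with
the multiplicative trait scales. Light-dependent or light-enhanced
courtship codes as 1; presence of wing pigmentation codes as 1.

## Known limitations

λ̂ on small trees (< 20 tips) is noisy and frequently hits a boundary;
the permutation test's resolution is 1/(n_perm + 1); PGLS assumes the
binary predictors are fixed covariates (no phylogenetic logistic or
threshold model is provided); tree inference itself, image-based counting
and 3D segmentation are out of scope — the package consumes a tree, it
does not build one.
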
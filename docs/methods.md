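# Methods

This note documents the models, the synthetic-data generator, the sampler,
the numerical conventions, and the deliberate design choices behind
`colonyqg`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Trait construction

A nest record is one breeding attempt: female id, season (year), island
(1–6), coordinates `x ∈ [0, 10.7]` and `y ∈ [0, 4.6]` metres inside the
island rectangle, laying date (day-of-year of the first egg of the first
clutch), and age in years. One record per female per year.

**Active-neighbour count.** For a focal nest, the number of other nests on
the same island within a radius (default 2 m, ties at the radius included)
whose clutch was initiated in the closed window
`[laying_date_focal − 28, laying_date_focal]` days. The window is
one-sided — a neighbour laying *after* the focal never counts — except
that same-day layers count each other mutually. Four weeks is the span
between first egg and last hatching, when nest attendance is maximal.
Islands are treated as socially separate (they are separated by walls and
a 0.9 m gap); a global-coordinates mode that bridges the gaps exists but
is off by default.

**Covariates.** Island density at breeding = nests initiated on the focal
island in the same window (equals the neighbour count at infinite radius);
colony density = breeding pairs that year, computed from the records; wall
distance = `min(x, 10.7 − x, y, 4.6 − y)`.

**Filters.** `known_age` removes every record of females whose age is ever
unknown. `presumed_dead` additionally keeps only females not observed in
either of the two most recent seasons. Trait covariates are computed from
the *complete* nest map before filtering (a removed focal female still
counts as someone's neighbour); the age partition and standardization are
computed on the analysed records.

## 2. Covariate preparation

**Within-subject centring.** `mean_age` is the female's mean age over her
analysed records; `delta_age = age − mean_age`. The between-individual
slope captures selective (dis)appearance and cohort effects; the
within-individual slope is the ageing signal proper; their posterior
difference is the selective-disappearance test, computed per posterior
sample.

**Standardization** is mean 0, population sd (ddof 0) 1. A `sd_multiples=2`
switch gives the two-sd (Gelman) convention; one sd is the default because
the primary reporting convention here is variance-standardized covariates.
Age itself enters the partitioned model in raw years and enters the
random-regression models standardized (`age_std`), so that the intercept
variance refers to the average age.

**Age classes** for heterogeneous residuals are age quintiles (ties to the
lower bin, empty bins collapsed with a warning). The class boundaries are a
package convention; five classes follow the standard practice of modelling
residual heterogeneity before interpreting random-slope variance.

## 3. Pedigree and relationship matrix

Pedigrees are (individual, sire, dam) triples, topologically sorted at
construction; unknown parents are empty fields in files. Cycles and
duplicate ids are hard errors; parents never listed as individuals are
auto-promoted to founders. Pruning keeps phenotyped individuals and all
their ancestors. `max_depth` counts parent–offspring links on the longest
founder-to-descendant path (founders = depth 0); paternities/maternities
count known-parent links in the (possibly pruned) pedigree.

**A** is built by the tabular method (`A_ii = 1 + A_{s,d}/2`,
`A_ij = (A_{j,s} + A_{j,d})/2`, unknown parents contributing zero) as a
dense array at all sizes; pedigrees here are far below the size where a
sparse representation would pay, and A fills in anyway once families are
connected. The test suite checks it entrywise (tolerance 1e−12) against an
independent memoized kinship recursion, and checks positive
semidefiniteness.

In the sampler, genetic effects are represented only for phenotyped
females: the marginal prior of their breeding values is `V_A` times the
corresponding *submatrix* of A, so latent ancestor effects are never
instantiated (and no A-inverse is ever formed — ancestors influence the
analysis through the relatedness they induce among phenotyped females).

## 4. The animal models

Counts are Poisson-lognormal:

    y_i ~ Poisson(exp(eta_i)),
    eta_i = x_i' beta + a_f + pe_f + u_year + u_island + e_i,
    a ~ N(0, V_A A),  pe, u_year, u_island iid,  e_i ~ N(0, V_resid),

with `e_i` the observation-level overdispersion term; `V_resid` may be
heterogeneous over the five age classes. The partitioned model's fixed
effects are mean age, delta age, their product, and standardized year,
colony density and island density (plus laying date and wall distance in
the extended variant). Random-regression models replace the individual
intercepts with (intercept, slope) pairs over `age_std`: one unstructured
2×2 covariance per female (I×Age), or a genetic block with covariance
`A ⊗ G2` plus an independent permanent-environment 2×2 block
(G×Age + PE×Age), always with the five-class residual.

**Derived parameters.** Per posterior sample (never as ratios of
summaries): `V_P` = sum of all estimated random-component variances
including the overdispersion residual (fixed-effect variance excluded, so
ratios are conditional on the fixed effects, on the latent log scale);
`h2 = V_A/V_P`; `R = (V_A + V_PE)/V_P`; `CV_A = 100·sqrt(V_A)/mean(y)`
with the data-scale trait mean. The distribution-specific variance term
`ln(1/exp(eta_bar) + 1)` is deliberately not added to `V_P`: under the
latent-scale convention the component proportions are additive, which is
how the published decompositions that this package emulates sum to their
repeatability. Reaction-norm variance at gradient value `g` is
`V_int + 2g·COV + g²·V_slope`, per sample.

## 5. Sampler

Metropolis-within-Gibbs with a partially collapsed variance update; one
sweep is:

1. **Latent rates.** Given the linear predictor, the `eta_i` are
   conditionally independent with log-concave conditionals
   (`y·eta − exp(eta)` plus a Gaussian prior). All n sites are updated at
   once by Metropolis–Hastings with Gaussian *independence* proposals
   centred at the conditional mode (a few damped Newton steps) with the
   local curvature as precision; acceptance is ≈ 0.95 and eta decorrelates
   in about one sweep.
2. **Variance components, collapsed.** Scalar components are parameterized
   as log-variances; 2×2 blocks as (log V_int, log V_slope, atanh r), so
   positive-definiteness holds by construction. Their joint posterior
   *given eta only* — all fixed and random effects integrated out
   analytically — is evaluated through the same joint precision matrix
   `M = B'R⁻¹B + D⁻¹` used for the effect draw:
   `log|Σ| = log|R| + log|D| + log|M|` and
   `eta'Σ⁻¹eta = eta'R⁻¹eta − b'M⁻¹b` (matrix inversion lemma), one
   Cholesky per evaluation. The update is exact univariate slice sampling
   coordinate-by-coordinate (bounded stepping-out with a randomized budget
   split, then shrinkage) followed by adaptive joint random-walk Metropolis
   substeps whose proposal covariance is adapted during burn-in and frozen
   afterwards. Collapsing removes the funnel coupling that makes
   uncollapsed Gibbs nearly reducible for confounded components (genetic
   vs permanent environment); the slice pass handles the heavy-tailed
   marginals of few-level components (island: 6 levels; year).
3. **Effects.** One exact joint Gaussian draw of beta and every
   random-effect level from the cached factorization of M. Genetic terms
   are whitened through a Cholesky factor of (the phenotyped submatrix of)
   A, so D⁻¹ is built from scalars and 2×2 inverses only. The precision
   matrix is assembled from precomputed pedigree Gram matrices
   (`L' diag(m_c) L` per residual class and gradient power), gathers of
   L-columns for female-keyed blocks, and O(n) scatter-adds.
4. **Residual variances.** Conjugate inverse-gamma per age class.

Validity: step 2 + step 3 form a partially collapsed pair (draw variances
from p(v | eta), then effects from p(effects | v, eta)), each kernel
leaving the joint posterior invariant.

**Priors.** Fixed effects Normal(0, 1e8). Every random-effect standard
deviation gets a half-Cauchy(scale 10) prior — the half-t marginal family
that parameter-expanded variance priors induce — implemented directly on
the collapsed target rather than through a redundant working parameter.
Reaction-norm correlations are uniform on (−1, 1). The residual variances
get inverse-gamma(0.5, 0.05). Log-variances are truncated to [−20, 10] for
numerical safety. Doubling the half-Cauchy scale moves the variance
medians by well under 20% at the test problem sizes (checked in the
suite).

**Defaults.** `n_iter=17000, burn_in=2600, thin=12` stores 1200 samples and
was sized so that, on the package's synthetic benchmark, every variance
component reaches an effective sample size of at least 1000 with |lag-1
autocorrelation| < 0.1 — the convergence yardstick used throughout. The
test and acceptance fits use shorter explicit configurations, documented
where they are used.

**Gaussian family.** With `family="gaussian"` the response is the latent
variable itself (identity link, no Metropolis step); this path exists for
oracle testing against a direct REML optimizer and for DIC behaviour
checks, not as a user-facing analysis mode.

**DIC** uses the conditional-deviance convention:
`DIC = 2·Dbar − D(eta_bar)` with the deviance evaluated at the posterior
mean of the latent predictor. This is the representation under which the
observation-level overdispersion terms count toward model complexity; DIC
for hierarchical models is representation-dependent, so the convention is
part of the contract.

## 6. Posterior summaries

Modes come from a Gaussian KDE with two adjustments: the density is
reflected at the sample extremes (standard boundary correction, so
variance posteriors piled against zero report a mode at the boundary
rather than shifted off it), and the Scott bandwidth is widened 2.5× —
mode estimation wants more smoothing than density estimation (optimal rate
n^(−1/7) vs n^(−1/5)); a plain reference-bandwidth argmax is dominated by
sampling jitter on flat-topped posteriors. 95% intervals are
highest-posterior-density (shortest) intervals; ESS is arviz's spectral
estimate; lag-1 autocorrelation is computed directly.

## 7. The synthetic colony generator

The generator emulates the study system that motivates the package:

- six 10.7 m × 4.6 m islands; nests placed uniformly per island, with a
  sticky home island per female (switch probability 0.1/year, giving ~1.5
  islands per lifetime);
- 29 breeding seasons with entry years weighted by a linear ramp (colony
  growth); recruits enter at ages 2–4, first-season females receive
  stationary ages; annual survival 0.87, ages truncated at 27 — observed
  mean age ≈ 7.1 ± 4.3 years at study-scale settings;
- laying dates advance about 2 days per year of age, with among-year
  phenology shifts (sd 4 days) and individual scatter (sd 8 days), giving
  an annual-mean age/laying-date correlation around −0.45 (realizations
  vary roughly −0.15 to −0.65 at desk scale);
- a discrete-generation monogamous pedigree; breeding values follow the
  linear-time Mendelian-sampling recursion (founders iid N(0, G2);
  non-founders = parental midpoint + deviation with covariance
  `v_i·G2`, `v_i` from the parents' inbreeding read off the A diagonal),
  with a quadratic-time Cholesky draw of the exact joint `A ⊗ G2`
  distribution retained as a small-pedigree oracle;
- counts generated by the exact generative inverse of the fitted model,
  with the full latent decomposition of every observation stored so that
  white-box tests can reconstruct eta term by term.

Two parameter presets. `TrueParams()` is the recovery-testing calibration
(V_A 0.20, V_PE 0.10, V_year 0.05, V_island 0.02, V_resid 0.30 — large,
well-separated components). `default_study_params()` is the
study-condition emulation: latent magnitudes back-computed from the
published-style decomposition (h2 36.5%, PE 28.4%, year 9.2%, island 0.8%
of a total latent random variance of ~0.076, evolvability ≈ 2.5% at trait
mean ≈ 6.6), intercept 1.795, paper-style fixed effects (island density
0.67 per sd, laying date 0.19, wall distance 0.084), genetic
intercept–slope correlation ≈ +0.6 with nearly flat permanent-environment
slopes.

**What the generator does not emulate.** The trait is generated from the
Poisson-lognormal model itself, not from the nest geometry, so its upper
tail is heavier than a mechanical neighbour count bounded by local crowding
(synthetic sd ≈ 9–11 and occasional counts near 100, vs 5.8 and a maximum
of 37 in the kind of colony data it mimics); the geometric
`neighbour_count` column built from the simulated maps is available and
bounded, but carries no known ground-truth variance components. There is
no extra-pair paternity, no within-season re-nesting, no male phenotypes,
and no spatial clustering of nests by default (uniform placement is a
stand-in; a clustered option was considered and left out as nothing
downstream consumes it). Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to the ways real colony data violate them.

## 8. Benchmark sizes

All MCMC benchmarks are desk-scale by design, sized to keep the default
test run in minutes on one core:

- variance recovery and age-partition recovery: ~100 phenotyped females,
  ~500 observations, 3-generation pedigrees (2 offspring/pair), 6
  replicates with coverage thresholds at 5/6 (≈ the 85–90% fractions the
  corresponding full-scale checks would use);
- genotype-by-age recovery: ~112 females over 29 seasons with full-sib
  families (3 offspring/pair) — sibships matter, a one-daughter-per-family
  pedigree leaves the genetic-vs-permanent-environment slope attribution
  underpowered; 6 replicates, sign threshold 5/6 plus a one-sided t-test
  of the posterior-mean correlations;
- the selective-disappearance contrast is detected at this scale through
  the replicate-level sign/t-test of contrast medians, not through
  per-replicate credible intervals (whose full-scale counterparts are an
  order of magnitude narrower);
- the convergence yardstick runs the default chain on a ~330-observation
  benchmark.

`scripts/acceptance.py` runs a single end-to-end study at ~160 females /
~850 observations / 29 seasons with the study-condition preset and short
explicit chains, and reports descriptives, trends, the variance
decomposition, age effects and the genotype-by-age summaries.

## 9. Known limitations

- Desk-scale posteriors are wide; point recoveries of variance ratios can
  sit a third away from truth in any one replicate even when calibration
  is correct.
- DIC is reported under one fixed convention (see §5) and inherits the
  general caveats of DIC for hierarchical models.
- The trend module's count regression is quasi-Poisson on the raw counts
  with a year covariate (an `annual_means` switch exists); its
  data-scale confidence interval comes from normal-approximation parameter
  draws, and no fully Bayesian trend model is provided.
- Heterogeneous residual classes are assumed uncorrelated, and residual
  variances get plain conjugate updates (no collapsed move), so their
  effective sample sizes are the lowest of all monitored parameters.
- The CLI covers the pipeline stages; multivariate (multi-trait) models,
  male/paternal effects and frequentist fitting paths are out of scope.
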
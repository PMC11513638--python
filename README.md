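# colonyqg

Quantitative genetics of the social environment in breeding colonies:
neighbour-density traits from nest maps, within-subject age partitioning,
and pedigree-based Bayesian Poisson animal models with genotype-by-age
random regressions.

## The scientific problem

In colonially breeding birds such as common terns, the number of actively
breeding neighbours around a nest is a key axis of the social environment:
it shapes competition, disease risk and social interaction. Long-term
colony studies ask three questions about this trait:

1. **Social ageing.** Does the number of neighbours change with a female's
   age, and is the change a within-individual process (birds move to the
   edges as they age) or a between-individual one (birds with many
   neighbours disappear from the population earlier — *selective
   disappearance*)?
2. **Heritability.** Do consistent individual differences in the social
   environment have an additive genetic basis?
3. **Heritable ageing rates.** Do individuals — and genotypes — differ in
   the *slope* of their age-specific decline (I×Age and G×Age
   interactions), and do intercepts and slopes correlate (a positive
   correlation produces a *fanning-out* of genetic variance with age)?

`colonyqg` implements this full analysis pipeline and a synthetic colony
generator with known ground truth, so that every stage — trait
construction, age partitioning, and the MCMC animal models — is testable
without any field data.

## The model

The trait is a count, modelled as overdispersed Poisson on a log link:

    y_i ~ Poisson(exp(eta_i))
    eta_i = x_i' beta + a_{f(i)} + pe_{f(i)} + u_{year(i)} + u_{island(i)} + e_i

with additive genetic values `a ~ N(0, V_A A)` (A the pedigree-derived
additive relationship matrix), permanent-environment, year and island
intercepts, and an observation-level Gaussian residual `e_i` (the
overdispersion term). Age enters through within-subject centring: each
female's mean age (between-individual effect) and her annual deviation from
it, delta age (within-individual effect); the posterior of their difference
is the selective-disappearance test. Derived parameters on the latent
scale: repeatability `R = (V_A + V_PE)/V_P`, heritability `h2 = V_A/V_P`
(V_P = sum of all estimated random components), and evolvability
`CV_A = 100 sqrt(V_A) / mean(y)`.

Random-regression models replace the intercepts with (intercept, slope)
pairs over standardized age — per female (`I×Age`), or split into an
additive genetic block with covariance `A ⊗ G2` plus an independent
permanent-environment block (`G×Age + PE×Age`) — with five heterogeneous
residual variances over age classes, and DIC for model comparison.

The sampler is written from scratch: Metropolis-within-Gibbs with
mode-centred independence proposals for the latent log rates, collapsed
(effects-integrated-out) slice-plus-Metropolis updates for the variance
components, and one exact joint Gaussian draw of all fixed and random
effects per sweep. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from colonyqg import (
    ModelSpec, MCMCConfig, default_study_params, simulate_dataset,
    fit_glmm_animal, variance_decomposition, posterior_contrast,
)

# simulate a 29-season colony with study-condition parameters
truth = default_study_params(seed=1)
ds = simulate_dataset(truth, n_founders=40, n_generations=3,
                      offspring_per_pair=3, n_years=29,
                      unknown_age_frac=0.0, seed=1)
A = ds.pedigree.prune(ds.nests["female_id"].unique()).a_matrix()

cfg = MCMCConfig(n_iter=2600, burn_in=800, thin=2, seed=1,
                 variance_substeps=2, slice_interval=3)
chains = fit_glmm_animal(ds.nests, A, ModelSpec(), cfg)
decomp = variance_decomposition(chains)
print(decomp.summary().round(3))
```

On this synthetic colony (841 observations of 162 females) the run prints:

```
                mode  median  hpd_lo  hpd_hi
quantity
h2             0.225   0.271   0.002   0.594
repeatability  0.543   0.543   0.378   0.706
prop_pe        0.000   0.261   0.000   0.503
prop_year      0.069   0.078   0.024   0.187
prop_island    0.000   0.033   0.000   0.230
prop_resid     0.298   0.307   0.195   0.452
cv_a           2.107   2.042   0.744   3.460
v_p            0.113   0.115   0.084   0.152
```

so the model attributes about 54% of the latent phenotypic variance to
consistent individual differences and roughly a quarter (wide interval at
this desk scale) to additive genetic effects, with an evolvability near
2.1% — consistent with the generative values of `default_study_params`
(h2 36.5%, R 64.9%, CV_A ≈ 2.5%, total latent variance 0.076). The
posterior contrast of the two age slopes
(`posterior_contrast(chains["beta:mean_age"], chains["beta:delta_age"])`)
is the selective-disappearance test; here it prints median −0.001 with 95%
HPD [−0.047, 0.049] — no detectable difference at this sample size.

A command-line interface mirrors the stages:

```bash
colonyqg simulate --out colony --seed 1
colonyqg build-trait --nests colony/nests.csv --out trait.csv --radius 2
colonyqg trend --table trait.csv --response neighbours --count-column count
colonyqg all --out run_dir --seed 1
```

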
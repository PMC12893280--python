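# Methods

## Model

`popthreat` models mean-centered log abundance of each population time
series as Gaussian with a linear trend structure:

```
y_t ~ Normal(mu_t, sigma)
mu_t = X_t beta + (r_S + r_P + r_L) * year_t + rho * eps_{t-1}
eps_t = y_t - (X_t beta + (r_S + r_P + r_L) * year_t)
```

* **Fixed effects.** `X` contains an intercept, centered year, one binary
  indicator per observed threat combination and each indicator's product
  with centered year. An interaction indicator equals the product of its
  constituent single indicators (equivalently: it is 1 when the combination
  is a subset of the population's threat set). With `m` combination labels
  the matrix has `2 + 2m` columns; fully crossing with a `g`-level factor
  multiplies the count by `g`.
* **Random slopes.** Species (`r_S`), population (`r_P`) and site (`r_L`)
  slopes moderate only the year effect — per-series centering of the
  response pins every intercept at zero, so no random intercepts are
  needed. All are noncentered: `r = sigma_group * z` with `z ~ Normal(0,1)`;
  site slopes are additionally correlated, `r_L = sigma_L * L z`, where `L`
  is the Cholesky factor of the site proximity matrix.
* **Temporal correlation.** A single AR(1) coefficient `rho` multiplies the
  previous *within-series* residual. Lag-1 is defined on consecutive
  observations regardless of the calendar gap between them (a documented
  limitation for very gappy series); the first observation of a series has
  no lagged term. Submodels per system or taxon rebuild the proximity
  matrix on their subset and estimate their own `rho`.
* **Priors.** `beta, z ~ Normal(0,1)`; `sigma, sigma_S, sigma_P, sigma_L ~
  Exponential(1)`; `rho ~ Normal(0, 0.25)` (0.25 is a standard deviation).
  The rho prior keeps essentially all mass inside (-1, 1), so no hard
  constraint is imposed.

## Data preparation

Inclusion filters: inclusive calendar span `last - first + 1 >= 10` years,
at least 5 observations, and documented threat status (each threshold is a
parameter). Both year and log abundance are centered at their within-series
means; centering is verified to remove the mean to < 1e-10. Series
containing zero abundances receive an offset of 1% of the series mean on
every observation before the log (recorded per series); positive-only
series are never offset. An alternative `centering="raw"` mode models the
mean-centered raw abundance without a log transform, since it is ambiguous
whether centering should precede or follow the transform; log-then-center
is the default because the response is log abundance.

## Spatial proximity

Site coordinates are rounded to the nearest integer degree (halves away
from zero); populations in the same one-degree cell share a site. Pairwise
Haversine distances (sphere radius 6371 km) are mapped to proximities by
`1 - D/max(D)` — the minimal transform with 1 for coincident and 0 for the
most distant pair; an exponential kernel `exp(-D/l)` is available as an
alternative. Since the linear transform is not guaranteed positive
semidefinite, negative eigenvalues are clipped to zero, the diagonal
re-normalized to one, and a nugget (default 1e-6) added to the diagonal;
coincident-only site sets fall back to the identity. The repaired matrix
always admits a Cholesky factor (escalating jitter as a last resort).

## Sampler

The model is conditionally Gaussian: given `theta = (sigma, sigma_S,
sigma_P, sigma_L, rho)`, the stacked coefficient vector `c = (beta, z_S,
z_P, z_L)` has a standard-normal prior and enters the mean linearly.
Whitening the AR(1) structure (`u_t = r_t - rho * r_{t-1}` within each
series; a unit-determinant bidiagonal operator) reduces the likelihood to
iid Gaussian, after which `c` is integrated out in closed form via the
matrix determinant lemma. Sampling then proceeds in two exact stages:

1. an adaptive random-walk Metropolis chain on the 4–5 dimensional marginal
   posterior of `theta` (log-scale for the sigmas with the Jacobian
   included; Haario empirical-covariance proposals and Robbins–Monro
   step-size tuning toward 30% acceptance during warmup, frozen after);
2. at every post-warmup iteration, a draw of `c` from its exact Gaussian
   conditional `N(M^-1 b, sigma^2 M^-1)` with `M = sigma^2 I + A'A` for the
   whitened, scale-adjusted regressor matrix `A`.

The composition samples the joint posterior exactly (marginal-then-
conditional); there is no approximation of the coefficient block and no
gradient computation. The marginal is low-dimensional and well-behaved, so
short chains mix adequately; each likelihood evaluation costs one `n x p`
whitening pass plus one `p x p` Gram factorization. Chains are seeded
independently from a single SeedSequence: identical spec + seed gives
bit-identical draws.

Defaults mirror a full-scale setting (4 chains x 5000 iterations, 2500
warmup); `ModelSpec.desk()` (2 x 1500, 750 warmup) is the profile used
throughout the tests and the acceptance pipeline. Reported draw counts are
post-warmup (`chains x (iterations - warmup)`).

Diagnostics report rank-normalized split-Rhat (flagging > 1.01) and arviz
bulk/tail ESS per parameter. Divergent transitions are an HMC concept; the
Metropolis sampler reports per-chain acceptance rates instead and a
`divergences` field fixed at zero. Posterior predictive checks simulate
replicated responses with the AR(1) recursion and summarize raw and
whitened residual lag-1 autocorrelation, residual mean, and a
variance-constancy slope (squared residuals on year).

## Trends and downstream analyses

A **trend** is the per-draw unweighted mean of successive difference
quotients of predicted log abundance over a strictly increasing year grid.
Predictions for a context (a threat combination, a population, a scenario)
are generated on a unit-spaced integer grid spanning the relevant years, so
gaps only arise if explicitly requested; for this model's linear predictors
the derivative is grid-independent and equals the least-squares slope on
noiseless input. Percent per year uses the multiplicative transform
`100*(exp(trend)-1)` (a log-linear model implies multiplicative change); a
linear `100*trend` option exists behind a flag. Summaries report 50/80/95%
equal-tailed intervals.

**Interaction classification.** The additive null is the sum of individual
effects: the additive prediction switches off every interaction column
among the combination's members (indicator and year twin together); the
interactive prediction leaves them on. The per-draw difference
(interactive − additive) is summarized by an equal-tailed CI at the chosen
level (default 80%): covering zero → additive, entirely negative →
synergistic (interactions worsen the decline), entirely positive →
antagonistic. Equal-tailed intervals are nested, so a combination
non-additive at one level is non-additive at every smaller level
(`sensitivity_scan` exposes this). Per-threat class shares support two
weightings: one vote per combination (default), or a certainty-weighted
"draw" mode in which a non-additive combination contributes mass equal to
the posterior probability of its verdict's direction and the remainder
counts as additive — a plausible way fractional percentages arise, but
neither mode is canonical.

**Influence decomposition.** Three trend posteriors: null (no threats,
random effects zero), random (no threats, all random-effect identities,
predictions averaged across series into a marginal posterior) and fixed
(every combination column set to one, conditional). The contribution
distributions are random−null and fixed−null per draw; a distribution at
zero means no contribution to trend direction.

**Counterfactuals.** (1) drop unthreatened populations; (2) zero every
design column whose combination contains a removed threat; (3) re-estimate
each population's trend (including its random slopes) on its own year grid
and pool per-population medians into the scenario distribution. Baseline
and scenario use identical draws, so differences are paired and an empty
removal set is bit-identical to baseline. Relative change is
`100*(cf - base)/|base|` on the pooled medians (mean mode available); a
zero baseline falls back to the absolute difference with a flag.

## Synthetic-data generator

The generator simulates forward from the model itself: sites uniform on
longitude and on latitude −55° to 70° (the monitored latitudes), spatially
correlated site slopes through the same proximity construction the model
uses, AR(1) residuals (innovation sd `sigma`, first residual ~ N(0, sigma)),
and abundances exponentiated from log space so they are positive by
construction (zeros can only enter via deliberate corruption). Spans are
log-normal with median 25 years, clipped to 10–65; interior years are
dropped at a configurable missingness rate (default 0.3) with first and
last retained, and at least 5 points guaranteed — every emitted series
passes the inclusion filters by construction.

Threat sets: each of the six categories enters independently with its
marginal prevalence (defaults: disease 3.04%, invasive 5.69%, climate
change 6.07%, pollution 7.16%, habitat loss 27.20%, exploitation 30.60%),
capped at three threats per series. These six marginals are mutually
inconsistent with also forcing a 20% unthreatened share (the implied mean
threat count among threatened series would fall below one), so the
unthreatened share is emergent (~40% under the defaults). An explicit
`threat_sets` override supports designed scenarios.

Default trend truth: a no-threat year slope of +0.0169 and single-threat
moderations (−0.0211 to −0.0788) whose implied percent-per-year trends
match the reported single-threat medians this generator emulates;
interaction coefficients default to zero (additive truth). Random-slope
scales default to `sigma_S = sigma_P = 0.02`, `sigma_L = 0.01` (a few
percent per year of between-group trend spread — large enough to matter,
small enough that fixed effects remain estimable at ~100 series);
`sigma = 0.3`, `rho = 0.3`. Desk-scale size defaults: 24 species x 5
populations, 40 sites (120 series, ~3000 observations), the size used by
the recovery study and acceptance pipeline.

`recovery_report` tabulates posterior median, bias and 90%-interval
coverage per parameter against the realized truth. `classifier_replicates`
runs the interaction classifier over many simulated replicates while
holding hyperparameters at the generator truth, so each replicate's
coefficient posterior is exactly Gaussian and can be re-drawn from one
precomputed factorization — hundreds of replicates run in seconds. This
harness tests the classifier's calibration (null truth → mostly additive at
the CI's nominal rate, up to binomial noise across replicates) and
detection (strong negative truth → synergistic), not the MCMC itself, which
the recovery study covers.

What passing tests do **not** show about real data: the generator draws
threats independently of space, taxon and time, has no observation-effort
artifacts, no threat-severity variation, no nonlinear dynamics, and
linear-in-log-abundance truth — so tests demonstrate correctness of the
machinery under the model's own assumptions, not robustness to their
violation.

## Known limitations

* **Attenuated rho.** Per-series mean-centering of the response makes the
  centered residuals slightly non-AR(1); with ~25-point series the
  posterior for `rho` concentrates below the generating value by roughly
  `(1+3 rho)/T` (≈ 0.07 at `rho = 0.3`, T = 25) — the classic short-panel
  demeaning bias. Trend coefficients are unaffected (fixed-effect interval
  coverage in the recovery study is nominal). A contrast-based likelihood
  would remove the bias but would change the model's stated observation-
  level density, so the plain form is retained and the bias documented.
* AR(1) treats consecutive observations as lag-1 regardless of calendar
  gaps; `rho` is shared across all series within a model.
* The proximity repair (eigenvalue clipping) is an engineering choice; the
  linear distance transform is not a valid covariance by construction.
* Counterfactuals are model predictions under threat-column deletion, not
  causal effects of management.
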
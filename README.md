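# popthreat

Hierarchical Bayesian analysis of vertebrate population trends under single
and multiple interacting threats.

Global conservation assessments usually rank threats (habitat loss,
exploitation, climate change, invasive species, pollution, disease) by how
often they are reported, not by how strongly they are associated with
population declines. `popthreat` implements a population-level alternative
for Living Planet Database (LPD)-style abundance time series annotated with
0–3 threat categories: a multilevel Gaussian trend model whose posterior
supports

* per-threat-combination **trend estimates** (the mean derivative of
  predicted log abundance, reported as % per year),
* classification of each multi-threat combination as **additive,
  antagonistic or synergistic** by differencing interactive and additive
  trend predictions,
* an **influence decomposition** separating threat (fixed-effect) from
  spatial/temporal (random-effect) contributions to trends, and
* **counterfactual scenarios**: predicted trends of the threatened
  populations had one or more threats been absent.

It is aimed at macroecologists and conservation scientists working with
long-term population monitoring data. Because the underlying LPD subset is
partly confidential, the package ships a synthetic-data generator that
simulates forward from the same model with known truth; all tests and the
acceptance pipeline run end-to-end on synthetic data.

## Model

For observation *t* of population *j* (species *i*, site *k*), with `y` the
per-series mean-centered natural log abundance and `year` the per-series
mean-centered calendar year:

```
y_ijk,t ~ Normal(mu_ijk,t, sigma)
mu_ijk,t = X beta + (r_S_i + r_P_j + r_L_k) * year_t + rho * eps_ijk,t-1
```

`X` is the binary threat-combination design matrix: intercept, year, one
indicator per observed combination (singles like `disease`, interactions
like `disease.exploitation`) and each indicator's product with centered year
— an interaction indicator is the elementwise product of its constituent
singles. `eps_t-1` is the previous within-series residual (AR(1); the first
observation has none). Random slopes are noncentered (`r = sigma_group * z`,
`z ~ N(0,1)`); site slopes are correlated through the Cholesky factor of a
proximity matrix built from integer-rounded site coordinates via Haversine
distance, normalized so 1 means coincident sites and 0 the most distant
pair. Priors: `beta, z ~ Normal(0,1)`; all scale parameters
`~ Exponential(1)`; `rho ~ Normal(0, 0.25)`.

Because the model is conditionally Gaussian, the sampler marginalizes the
whole coefficient block analytically and runs an adaptive Metropolis chain
on the five hyperparameters only, drawing the coefficients from their exact
Gaussian conditional at every kept iteration (see `docs/methods.md`).

## Worked example

```python
import popthreat as pt

# 120 synthetic series (24 species, 40 sites) with known truth
series, truth = pt.generate(pt.GeneratorConfig(seed=1))

model = pt.ThreatTrendModel.from_series(series)   # filters + design + proximity
res = model.fit(pt.ModelSpec.desk(seed=1))        # 2 chains x 1500 iter (750 warmup)

print(res.trend(()).summary())                    # no-threat trend
print(res.trend({"exploitation"}).summary())      # single-threat trend
v = res.classify_interaction("exploitation.habitat_loss")
print(v.verdict, v.median, (v.ci_low, v.ci_high))
sc = res.counterfactual({"exploitation"})
print(sc.baseline_median, sc.counterfactual_median,
      sc.relative_change_percent.value)
```

Output (abridged):

```
context  median  median_percent    lo50   hi50   lo80   hi80    lo95   hi95
   none  0.0112          1.1275 -0.0034 0.0264 -0.024 0.0464 -0.0501 0.0734
     context  median  median_percent    lo50    hi50    lo80   hi80    lo95   hi95
exploitation -0.0227         -2.2398 -0.0385 -0.0068 -0.0568 0.0142 -0.0831 0.0403
additive 0.0039 (-0.0144, 0.0203)
baseline median -0.0345  cf median -0.0076  rel change 77.9%
```

Read: populations without threats grow ~1.1 %/yr while those under
exploitation decline ~2.2 %/yr (80% interval still straddling zero at this
sample size); the exploitation x habitat-loss interaction is classified
additive (its 80% CI spans zero); and removing exploitation from the
threatened populations raises their median predicted trend from −0.035 to
−0.008 log units/yr, a 77.9% relative improvement. Against the generator
truth, 97% of the fixed-effect 90% credible intervals cover their true
values (`res.recovery_report(truth)`).

A thin CLI mirrors the pipeline:
`popthreat simulate --out synth.csv --seed 1`,
`popthreat prepare --input synth.csv --out tidy.csv`,
`popthreat fit --data synth.csv --out draws.json`.

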
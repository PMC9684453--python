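# phenoescape

Hierarchical Bayesian modelling of spring phenology from herbarium
specimen records, and projection of "spring light windows" — the
high-light period understory wildflowers enjoy between their flowering
and canopy closure — onto gridded climate under current and end-of-century
warming scenarios.

## Who this is for

Ecologists working with digitised herbarium collections who want to

* estimate the **phenological sensitivity** (days per °C) of canopy-tree
  leaf-out (LOD) and wildflower first-flowering (FFD) to average
  March–April temperature, per forest stratum and continent;
* compare sensitivities across strata and continents with the
  credible-interval-overlap rule;
* map the resulting spring light window, `LOD − FFD` (days), and its
  change under a warming scenario, masked to deciduous-forest cover.

## The model

Observed event day-of-year for specimen *i* of species *j* follows

```
doy_ij ~ N(mu_ij, sigma^2)
mu_ij  = beta0 + beta1 * SpringT_i + beta2 * Elevation_i + alpha_j
```

with vague priors `beta0, beta1, beta2, alpha_j ~ N(0, precision 1e-3)`
(variance 1000) and a uniform prior on the residual precision,
`1/sigma^2 ~ Uniform(0, 100)`. One model is fitted per stratum ×
continent by an in-package two-block Gibbs sampler: a joint conjugate
multivariate-normal update for all coefficients, and a truncated-gamma
update for the precision. `beta1` is the phenological sensitivity in
days per °C (negative = earlier events in warmer springs).

Because the intercept and the species offsets are confounded under
independent vague priors, reported intercepts are the identified
combination `beta0 + mean_j(alpha_j)` ("community intercept").

## Worked example

```python
from phenoescape import (MCMCConfig, PhenologyModel, SyntheticConfig,
                         simulate_records)

cfg = SyntheticConfig(n_species=6, n_per_species=200, beta1=-3.5,
                      sigma=5.0, seed=11)
records, truth = simulate_records(cfg)

model = PhenologyModel.from_records(records)
result = model.fit(MCMCConfig(n_chains=2, n_iter=2000, n_burnin=700,
                              thin=2, seed=3))
s = result.summarize()["beta1"]
print(f"beta1: {s.mean:+.3f} days/degC, 95% BCI [{s.lower:+.3f}, {s.upper:+.3f}]")
print(f"predictive r2: {result.predictive_r2():.3f}")
```

prints

```
beta1: -3.460 days/degC, 95% BCI [-3.543, -3.381]
predictive r2: 0.907
```

— the posterior mean recovers the generative sensitivity of −3.5 days/°C
and its 95% credible interval covers it; r² is the squared Pearson
correlation between posterior-mean predictions and observed day-of-year.

The full workflow (simulate or load records → temperature-window screen →
six stratum×continent fits → interval comparisons → gridded light-window
projection) runs from the command line:

```sh
phenoescape run --outdir myrun --seed 5
phenoescape summarize --outdir myrun
```

Real specimen tables are supplied as CSV
(`record_id, species, stratum, continent, lat, lon, elev_m, year, doy,
spring_temp_c`; rows before 1901 or with out-of-range values are rejected
into a diagnostics report), grids as NetCDF.

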
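# Methods

## Model

Each scored specimen contributes one observation: the day-of-year (DOY)
of a spring phenological event — leaf-out for canopy trees, first
flowering for understory wildflowers. DOY is modelled with a normal
likelihood whose mean is linear in the average March–April temperature
(°C) and elevation (m) at the specimen's location and year, plus a
per-species intercept offset:

```
doy_ij ~ N(mu_ij, sigma^2)
mu_ij  = beta0 + beta1 * SpringT_i + beta2 * Elevation_i + alpha_j
```

One model is fitted per forest stratum × continent, so `beta1` is a
stratum-and-continent-level sensitivity in days per °C. Assumptions
worth keeping in mind:

* the response to spring temperature is linear over the observed range
  (no chilling, photoperiod, or accumulation dynamics);
* records are conditionally independent given the covariates — no
  spatial or temporal autocorrelation term;
* one fixed forcing window (March–April) is used everywhere; the window
  screen (below) is a diagnostic justifying that choice, not part of the
  fit.

### Priors

All coefficients — including every species offset — get independent
`N(0, variance 1000)` priors; we state them in the precision
parameterisation (`precision 1e-3`) because that is the convention of
BUGS/JAGS-style engines and these are intended as vague, "slightly
informative" priors. The residual precision gets `1/sigma^2 ~
Uniform(0, 100)`, implemented literally: the Gibbs update for the
precision is a gamma draw truncated to (0, 100].

Giving the species offsets independent vague priors (rather than a
shared, estimated hyper-variance) is unusual for random effects: the
offsets are shrunk toward zero only negligibly, and the model intercept
is confounded with their mean. Only `beta0 + alpha_j` is
likelihood-identified. We therefore report the **community intercept**
`beta0 + mean_j(alpha_j)`, which is stable under reparameterisation and
species relabelling (tested); centering is applied at reporting time
only, never to the chain state.

### Sampler

Full conjugacy gives a two-block Gibbs scheme:

* **coefficients | precision** — the conditional is exactly
  `N(A^{-1} tau X'y, A^{-1})` with `A = tau X'X + 1e-3 I`; we draw the
  whole block jointly via a Cholesky solve of the (p × p) system built
  from precomputed sufficient statistics (`X'X`, `X'y`, `y'y`). Elevation
  enters in raw metres; the joint solve handles the resulting conditioning
  without rescaling covariates.
* **precision | coefficients** — `Gamma(n/2 + 1, rate SSE/2)` truncated
  to (0, 100], drawn by inverse CDF of the regularised incomplete gamma.
  With no data the conditional degenerates to the uniform prior itself,
  which is drawn directly.

Defaults: 3 chains × 20 000 iterations, 10 000 burn-in, thin 10
(3 000 retained draws); initialisation is a ridge least-squares solve
plus jitter (a prior draw is available). Split R-hat and bulk ESS are
computed per parameter (via ArviZ); any R-hat above 1.1 raises a
warning. Seeded runs are exactly reproducible; per-chain and per-group
seeds are spawned from one `SeedSequence`.

Sampler validation is part of the package (`phenoescape.validation`):

* with the precision fixed at truth each coefficient draw is an exact
  independent posterior draw, so sample moments are compared against the
  closed-form mean and covariance at 10 000 draws;
* a replicate simulate-and-refit study (default 100 replicates of 1 200
  records at `beta1 = −3.5`, `sigma = 5`) measures bias and 95%-interval
  coverage of the sensitivity.

## Inference rule

Posterior summaries use equal-tailed quantile credible intervals
(the default interval type of JAGS-style engines), not HPD. Two
parameters are declared *different* iff their 95% intervals are
disjoint; touching endpoints count as overlap. This is deliberately the
only inference rule in the package — no p-values, no multiplicity
adjustment.

Model fit is summarised by r², defined as the squared Pearson
correlation between posterior-mean predictions and observed DOY
(`1 − SSE/SST` is reported alongside but Pearson² is the headline).
Driver screening (`model_compare`) refits the model for candidate
covariate sets drawn from {spring temperature, winter temperature,
annual precipitation, spring precipitation, elevation} and ranks by DIC
(`Dbar + pD`); DIC and predictive r² are both reported because no single
criterion is canonical for this comparison.

## Temperature-window screen

All nine contiguous 1-, 2-, and 3-month mean-temperature windows within
February–May are correlated (Pearson, matching the linear model) with
DOY, pooled within stratum × continent. Groups smaller than 3 records
or with zero temperature variance are flagged in the output table, not
dropped. The screen is reported as a tidy CSV; the pipeline always fits
on the March–April mean.

## Projection

Posterior means of the community intercept, `beta1` and `beta2` are
pushed through aligned spring-temperature and elevation rasters to give
predicted DOY surfaces per stratum. The spring light window is
`LOD − FFD` (days), positive when flowering precedes leaf-out; its
change between scenarios is `ΔWindow = future − current`, so positive
values mean the window lengthens under warming (a flag flips the sign
convention if the opposite order is wanted). Cells with deciduous-forest
fraction below 1% are masked to nodata; masking is idempotent and
commutes with scenario differencing. Continental summaries are plain
cell means ± population s.d. over unmasked cells — no equal-area
weighting by default, since grid summaries are reported as simple
averages (a cos-latitude weighting could be added by the caller on the
exported arrays).

Community prediction aggregates species offsets as their arithmetic
mean within each stratum × continent fit (species-by-species pairing of
wildflowers and trees is a possible refinement, not implemented).

Grids are WGS84 decimal degrees, north-up, cell-centre registered, and
persisted as NetCDF (classic format via the SciPy backend); float32
payloads round-trip bit-exactly. Grids combined arithmetically must
share shape and geotransform exactly — there is no implicit resampling.

## Synthetic data

The generator inverts the analysis model, so every downstream stage is
testable without downloads:

* `doy = beta0 + beta1·T + beta2·E + alpha_j + eps`, with `alpha_j`
  drawn once per dataset and recorded in a manifest (they are estimands
  for recovery tests); the round-free real-valued DOY is kept in the
  manifest beside the integer DOY (round-half-even).
* Spring temperature = latitudinal gradient (−0.4 °C per degree north
  of 45°, 8 °C baseline) + 0.01 °C/yr trend + interannual noise whose
  s.d. is continent-specific (North America 2.5 °C, Europe/Asia 1.5 °C —
  North American springs are the most variable, which is also why fits
  there are better determined).
* Monthly Feb–May series: March and April split symmetrically about the
  spring mean (so their average reproduces it exactly); February and May
  are offset flanks with independent noise. This is what makes the
  window screen identifiable.
* Defaults: 6 species × 200 records, `beta0 = 145` (mid-May community
  intercept once covariate effects are added), `beta1 = −3.5` days/°C,
  `beta2 = 0.02` days/m (later events at elevation), `alpha_sd = 5`,
  `sigma = 5` days. The residual s.d. is a fixture choice — no empirical
  estimate of it is available to copy — set so that r² lands in a
  realistic range for herbarium data.
* Fixture grids are smooth deterministic fields (latitudinal temperature
  gradient, sinusoidal elevation and forest fraction) with the future
  scenario equal to current plus a uniform offset, and with cells both
  below and above the 1% forest threshold guaranteed.

What the generator does **not** emulate: spatial clustering of
collections, phenophase-scoring error, uneven species representation,
non-linear or chilling-dependent responses. Passing recovery tests
therefore show the estimator is correct *under the model's own
assumptions*, not that the model is adequate for any particular real
collection.

## Numerical choices and edge cases

* Truncated-gamma inverse-CDF draws clamp the uniform variate away from
  0/1 to avoid the incomplete-gamma inverse overflowing in the extreme
  tails; draws are clipped into the open support.
* Records failing validation (pre-1901 year, DOY outside 1–366,
  coordinates out of range, unparseable fields) are rejected row-by-row
  into a diagnostics table; `n_accepted + n_rejected = n_input` always.
* A species present in the index with no records keeps its prior — the
  fit warns and proceeds when there are fewer records than parameters
  (the priors regularise the solve).
* Problem sizes in the validation studies (500–2 000 records, 10 000
  draws, 100 replicates, ~2 000-iteration chains in the replicate loops)
  were chosen as the smallest sizes at which the Monte-Carlo error bands
  in those checks are meaningful.

## Known limitations

* No spatial-autocorrelation term; estimates inherit whatever spatial
  aggregation bias the input records carry.
* The interval-overlap rule is conservative relative to testing the
  posterior of a difference; it is used because it is the package's
  stated inference convention.
* DIC with vague independent priors on many species offsets can be
  erratic for tiny groups; comparisons are most meaningful at a few
  hundred records and more per group.
* Projection treats posterior means as plug-in values; parameter
  uncertainty is not propagated into the maps.
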
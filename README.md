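# cpuerecon

Catch-and-effort data reconstruction and CPUE standardization for a
seasonal offshore longline fishery, with a seeded synthetic-data generator
standing in for the (confidential) real fishery records.

## The problem

Stock assessments of large migratory tuna lean heavily on catch per unit
effort (CPUE, here fish caught per fishing day per trip) as a relative
abundance index. For small fleets with historically poor logbook coverage,
neither the catch (number of fish) nor the effort (fishing days) exists as
a clean series, so both must be reconstructed from indirect sources before
any standardization can begin:

1. **Fish numbers from landing weights.** Early market records give the
   offloaded weight but often not the count. Because single-fish landings
   are common and individual fish fall in a narrow 80–350 kg band, records
   in that band define an empirical weight-per-fish (WPF) distribution
   (lognormal fits better than normal by the two-sample Kolmogorov–Smirnov
   D). Summing k bootstrap draws from it (k = 1…50, 10,000 replicates)
   builds a simulated total-weight band per count, and a record with
   missing count draws its k in proportion to how often each count's
   simulated totals land in the record's 10-kg weight bin.
2. **Fishing days from vessel tracks.** On hourly geolocation data, a
   longline operating day shows a deployment leg, a soak, then a turn of
   120–180° into a slow retrieval leg, while a transiting vessel holds a
   near-constant heading. Three criterion families (any speed ≤ x kn;
   within-day path length < x km; maximum heading change ≥ x° at an h-hour
   resampling) are scored against labelled days with the sum (SSS) and
   absolute difference (DSS) of sensitivity and specificity and tuned by
   grid search — maximize SSS, break near-ties by smaller DSS.
3. **Fishing days from port logs.** For years without geolocation, fishing
   days per trip are predicted from at-sea days via zero-intercept
   regressions b = Σxy/Σx² fitted by port × vessel size class (no at-sea
   days ⇒ no fishing days), with a sequential ANOVA supporting the
   grouping and both R² conventions reported (the uncentered one implied
   by the through-origin fit flatters the fit).
4. **Delta-lognormal standardization.** Trip-level CPUE is zero-heavy, so
   the probability of a positive catch is fitted by a binomial GLMM (the
   zero-proportion model, ZPM) and positive catch magnitude by a Gaussian
   mixed model on log CPUE (the positive-catch model, PCM):

   logit P(catch > 0) = Year + Month (+ Vessel size + Area) + u_{Y×M},
   log CPUE⁺ = Year + Month (+ …) + u_{Y×M} + ε,  u ~ N(0, σ²_u) iid.

   Terms are chosen backward (fixed mains; Year always kept) then forward
   (random year-by-factor interactions) under AIC or BIC. The annual index
   is the product of the two components' year least-squares means
   (observation-count-weighted margins), the lognormal one back-transformed
   with the exp(σ²/2) lognormal bias correction:
   Index_y = p̂_y · exp(μ̂_y + σ̂²/2).
5. **Design comparison by cross-validated R².** Repeated random half
   splits refit the final models on the build half and predict the
   validation half stochastically (a uniform draw against the fitted
   positive probability gates the back-transformed PCM prediction); the
   squared Pearson correlation of observed and predicted CPUE, pooled over
   grounds, compares fitting each fishing ground separately versus one
   model with area as a factor.

Every stage is driven by the `simulate` module, which generates landings,
hourly tracks with ground-truth fishing-day labels, port entry/exit trips,
and zero-inflated CPUE tables with known effects, so all recovery claims
are testable without any confidential data.

## Worked example

```python
import cpuerecon as cr

cfg = cr.SimConfig(seed=7)

# tune the fishing-day criterion against labelled synthetic tracks
points, labels = cr.gen_tracks(cfg.replace(n_vessels=10, n_days=50))
days = cr.split_days(points)
best, table = cr.grid_search(days, labels, "direction")
print(f"direction optimum: {best.threshold:.0f} deg per {best.interval_h} h, "
      f"SSS = {table['SSS'].max():.3f}")

# standardize a synthetic CPUE series
rec, truth = cr.gen_cpue(cfg.replace(n_trips=10_000))
fit = cr.DeltaLognormalModel(
    rec,
    cr.ModelSpec("ZPM", ("year", "month")),
    cr.ModelSpec("PCM", ("year", "month")),
).fit()
print(fit.summary())
```

prints

```
direction optimum: 15 deg per 1 h, SSS = 2.000
Delta-lognormal CPUE standardization

Zero-proportion model: Year + Month  n=10000  AIC=12249.1  BIC=12371.7  converged=True
Positive-catch model: Year + Month  n=6987  AIC=13064.2  BIC=13187.5  converged=True

  year   p_pos      mu    index    rel
  2001   0.726   1.020    2.430  2.095
  2002   0.703   1.159    2.705  2.332
  ...
  2014   0.684  -0.949    0.320  0.276
  2015   0.670  -0.835    0.351  0.303
```

The heading-change criterion separates the synthetic fleet's fishing days
perfectly (SSS = 2; on real tracks the optimum sits near 90° at 5-h
resampling with SSS ≈ 1.6). In the standardization table, `p_pos` is the
ZPM year effect (probability of a positive trip), `mu` the PCM year effect
on the log scale, `index` their bias-corrected product, and `rel` the
index scaled to its series mean — the declining `rel` series recovers the
generator's declining abundance trajectory (correlation ≥ 0.99 with the
true year effects at this sample size).

A `cpuerecon` command-line tool exposes the same stages
(`simulate`, `impute-counts`, `classify`, `tune`, `effort`, `standardize`,
`evaluate`, `pipeline`); `cpuerecon pipeline --seed 0 --out-dir out/` runs
them end to end and writes a manifest with output hashes.

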
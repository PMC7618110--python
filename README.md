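# tempmort

Two-stage distributed-lag non-linear modelling (DLNM) of
temperature–mortality associations, with minimum-mortality-temperature
estimation and cold/heat attributable burden.

The package is aimed at environmental epidemiologists analyzing
multi-location daily time series of all-cause deaths and ambient
temperature — the setting of national studies in which each
administrative unit gets its own exposure–lag–response surface and the
units are then pooled. It provides, as a tested library plus CLI:

1. **Stage 1** — per-location quasi-Poisson regression with a DLNM
   cross-basis: a cubic B-spline over temperature (knots at the
   location's 10th/75th/90th percentiles) tensor-multiplied with a
   natural cubic spline over lags 0..L, controlling for seasonality
   (natural cubic spline of time, 6 df/year), day of week, and
   relative humidity (optionally PM2.5). The fit is reduced to the
   overall cumulative exposure–response
   `f(x) = sum_l s(x, l)` with its covariance.
2. **Stage 2** — multivariate random-effects meta-regression
   `theta_i ~ N(X_i beta, S_i + Psi)` across locations with seven
   meta-predictors, estimated by REML; Wald tests per predictor,
   multivariate Cochran Q and I², and BLUPs that shrink each location
   toward the pooled prediction.
3. **Attribution** — the minimum mortality temperature (MMT) as the
   arg-min of each BLUP curve on the location's percentile grid,
   backward attribution `AN_t = y_t (1 - exp(-eta_t))` of each day's
   exposure history re-centered at the MMT, cold/heat and
   percentile-band splits, and empirical Monte-Carlo confidence
   intervals from jointly sampled coefficient ensembles.
4. **Synthetic data** — a generator with a known J/U-shaped risk
   surface, separate acute-heat and slow-cold lag profiles, and exact
   truth (curves, MMT, attributable fractions), so the whole pipeline
   is testable end-to-end.

See `docs/methods.md` for the model, estimation details and design
choices.

## Worked example

```python
from tempmort.synthetic import paper_like_scenario, simulate_scenario
from tempmort.pipeline import RunConfig, run_two_stage

study = simulate_scenario(paper_like_scenario(seed=7))   # 32 locations x 10 years
config = RunConfig(max_lag=7, n_sim=1000, seed=99)
bundle = run_two_stage(study.series, study.covariates, config)

het = bundle.heterogeneity()
print(f"I2 = {het['I2']:.1f}%  (Q = {het['Q']:.0f} on {het['Q_df']} df)")
c = bundle.country
for cat in ("total", "cold", "heat"):
    lo, hi = c.af_ci[cat]
    print(f"AF {cat:5s} {c.af[cat]:5.2f}%  (95% CI {lo:.2f} to {hi:.2f})")
```

prints (seed 7, one run of the default preset):

```
I2 = 19.7%  (Q = 179 on 144 df)
AF total  3.51%  (95% CI 2.73 to 4.14)
AF cold   0.14%  (95% CI 0.09 to 0.19)
AF heat   3.37%  (95% CI 2.62 to 4.01)
```

i.e. about 3.5% of all deaths in this simulated study are attributable
to non-optimal temperature and the burden is dominated by heat — the
expected outcome for the generator's default J-shaped truth, whose
heat limb (log-RR 0.12 at the 99th percentile) is three times its cold
limb and whose cold contribution emerges over lags mostly beyond the
7-day analysis window. I² reflects the preset's between-location
variation in limb heights.
`bundle.location_table()` gives the per-location MMT/MMP and
cold/heat burdens; `bundle.write(outdir)` serializes every table as
TSV.

The same analysis from the shell:

```sh
tempmort simulate --seed 7 --out sim/
tempmort run --series sim/series.tsv --covariates sim/covariates.tsv \
             --seed 99 --out results/
tempmort sensitivity --series sim/series.tsv --lags 7,14,21,28 \
             --seed 99 --out sensitivity.tsv
```

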
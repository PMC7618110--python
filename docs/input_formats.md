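# Input and output formats

All files are tab-delimited text with a header row; dates are ISO 8601.

## Daily series (consumed by `fit` / `run`; emitted by `simulate` and preprocess)

Long format, one row per location-day, gapless calendar within each
location (missing observations are empty cells, never absent rows):

| column        | type    | description                                  |
|---------------|---------|----------------------------------------------|
| `location_id` | string  | location identifier                          |
| `date`        | date    | calendar day                                 |
| `deaths`      | integer | all-cause death count (>= 0; blank = missing)|
| `tmean`       | float   | daily mean temperature, degrees C            |
| `rh`          | float   | daily mean relative humidity, % (optional)   |
| `pm25`        | float   | daily mean PM2.5, ug/m3 (optional)           |

## Location covariates (consumed by `run` / `meta`)

One row per location; all seven predictors required when supplied:

`location_id`, `avg_temp` (degC), `temp_range` (degC),
`pw_latitude` (degrees), `pw_elevation` (m), `pop_density` (1/km2),
`avg_rh` (%), `mpi` (%).

## Hourly weather (consumed by `preprocess`)

`timestamp` (ISO 8601, UTC), `t2m` (degC), `d2m` (degC), one row per
hour, already spatially averaged over the location. Gridded-reanalysis
extraction itself is out of scope.

## Reduced / BLUP curve files

Key-value text blocks written by `fit` and `meta` (`*_curve.tsv`,
`blup_curves/<location>.tsv`): exposure-basis family, degree, knots,
boundary, optional center, coefficient vector and covariance matrix —
everything needed to re-center and predict the curve downstream.

## Result tables (written by `run` / `attribute`)

* `locations.tsv` — per-location MMT, MMP (with boundary flag), and
  attributable deaths/fractions for total/cold/heat with 95% empirical
  CIs.
* `country.tsv` — aggregate burden by category (total, cold, heat,
  and the 1st/5th/10th/90th/95th/99th percentile bands).
* `heterogeneity.tsv`, `wald.tsv` — second-stage summaries.
* `config.yaml` — the fully-resolved run configuration, sufficient to
  reproduce every table byte-for-byte.
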
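"""Config-driven orchestration of the full two-stage analysis.

``run_two_stage`` chains: per-location quasi-Poisson DLNM fits ->
multivariate meta-regression -> BLUPs -> minimum-mortality-temperature
search -> attributable numbers/fractions with Monte-Carlo CIs ->
delimited output tables (per-location and country aggregate).
``sensitivity_grid`` repeats the run over a Cartesian grid of
modelling choices (lag window, seasonality df, PM2.5 adjustment,
period strata).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from . import stage1, stage2
from .stage1 import DailySeries, ModelConfig
from .stage2 import MetaInput, MetaModel

logger = logging.getLogger("tempmort")

__all__ = ["RunConfig", "ResultBundle", "run_two_stage", "sensitivity_grid"]

_ALLOWED_LAGS = (7, 14, 21, 28)
_ALLOWED_SEAS_DF = (4.0, 6.0, 8.0)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one end-to-end run."""

    max_lag: int = 7
    seasonal_df_per_year: float = 6.0
    var_degree: int = 3
    var_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    lag_knots: int | None = None
    use_rh: bool = True
    use_pm25: bool = False
    period: tuple[str, str] | None = None     # (start, end) stratum, inclusive
    meta_method: str = "reml"
    use_meta_predictors: bool = True
    n_sim: int = 1000
    seed: int = 12345
    strict_lags: bool = True

    def __post_init__(self) -> None:
        if self.strict_lags and self.max_lag not in _ALLOWED_LAGS:
            raise ValueError(f"max_lag must be one of {_ALLOWED_LAGS}")
        if self.strict_lags and self.seasonal_df_per_year not in _ALLOWED_SEAS_DF:
            raise ValueError(f"seasonal_df_per_year must be one of {_ALLOWED_SEAS_DF}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be positive")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            max_lag=self.max_lag,
            var_degree=self.var_degree,
            var_knot_percentiles=self.var_knot_percentiles,
            lag_knots=self.lag_knots,
            seasonal_df_per_year=self.seasonal_df_per_year,
            use_rh=self.use_rh,
            use_pm25=self.use_pm25,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        for key in ("var_knot_percentiles", "period"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ResultBundle:
    config: RunConfig
    fits: dict[str, stage1.Stage1Fit]
    failed: dict[str, str]
    meta: MetaModel
    blups: stage2.BlupSet
    mmt: dict[str, attr.MmtResult]
    attribution: dict[str, attr.AttributionResult]
    country: attr.AttributionResult

    def location_table(self) -> pd.DataFrame:
        """Per-location MMT/MMP and overall/cold/heat burden (the
        shape of the per-department results table)."""
        rows = []
        for loc, res in self.attribution.items():
            m = self.mmt[loc]
            row = {"location_id": loc, "mmt": m.mmt, "mmp": m.mmp,
                   "mmp_at_boundary": m.at_boundary}
            for c in ("total", "cold", "heat"):
                row[f"an_{c}"] = res.an[c]
                row[f"an_{c}_lo"], row[f"an_{c}_hi"] = res.an_ci[c]
                row[f"af_{c}"] = res.af[c]
                row[f"af_{c}_lo"], row[f"af_{c}_hi"] = res.af_ci[c]
            rows.append(row)
        return pd.DataFrame(rows)

    def category_table(self) -> pd.DataFrame:
        """Country-level burden by category (total, cold, heat and the
        temperature-percentile bands)."""
        return self.country.to_frame()

    def heterogeneity(self) -> dict:
        return stage2.heterogeneity(self.meta)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(self.config.to_yaml())
        self.location_table().to_csv(outdir / "locations.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        self.category_table().to_csv(outdir / "country.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        het = self.heterogeneity()
        wald_rows = [{"predictor": k, **v} for k, v in self.meta.wald.items()]
        meta_txt = {"method": self.meta.method, "I2": het["I2"], "Q": het["Q"],
                    "Q_df": het["Q_df"], "Q_p": het["p"]}
        pd.DataFrame([meta_txt]).to_csv(outdir / "heterogeneity.tsv", sep="\t",
                                        index=False, float_format="%.10g")
        if wald_rows:
            pd.DataFrame(wald_rows).to_csv(outdir / "wald.tsv", sep="\t",
                                           index=False, float_format="%.10g")
        curves = outdir / "blup_curves"
        curves.mkdir(exist_ok=True)
        blup_curves = self.blups.curves(_meta_input(self.fits, None))
        for loc, curve in zip(self.blups.location_ids, blup_curves):
            (curves / f"{loc}.tsv").write_text(curve.to_text())


def _meta_input(fits: dict[str, stage1.Stage1Fit],
                covariates: pd.DataFrame | None) -> MetaInput:
    ids = list(fits.keys())
    pred = None
    if covariates is not None:
        missing = [i for i in ids if i not in covariates.index]
        if missing:
            raise ValueError(f"covariate table lacks rows for {missing}")
        pred = covariates.loc[ids, list(stage2.META_PREDICTORS)]
    return MetaInput(location_ids=ids,
                     curves=[fits[i].reduced for i in ids],
                     predictors=pred)


def run_two_stage(series_list: list[DailySeries],
                  covariates: pd.DataFrame | None,
                  config: RunConfig) -> ResultBundle:
    """Run the complete analysis over a set of locations.

    Locations whose first-stage fit fails are logged and excluded from
    the second stage; fewer than three successes aborts.
    """
    if config.period is not None:
        series_list = [s.slice_period(*config.period) for s in series_list]
    mc = config.model_config()

    fits: dict[str, stage1.Stage1Fit] = {}
    failed: dict[str, str] = {}
    for s in series_list:
        try:
            fits[s.location_id] = stage1.fit_location(s, mc)
            logger.info("stage1 %s: fitted (phi=%.2f, %d days)",
                        s.location_id, fits[s.location_id].dispersion,
                        fits[s.location_id].n_days_used)
        except Exception as e:            # noqa: BLE001 - per-location isolation
            failed[s.location_id] = str(e)
            logger.warning("stage1 %s: failed (%s)", s.location_id, e)
    if len(fits) < 3:
        raise RuntimeError(f"only {len(fits)} locations fitted successfully; "
                           f"need at least 3 for the second stage")

    meta_in = _meta_input(fits, covariates if config.use_meta_predictors else None)
    meta = stage2.fit_meta(meta_in, method=config.meta_method)
    blups = stage2.blup(meta, meta_in)
    blup_curves = {loc: c for loc, c in zip(blups.location_ids, blups.curves(meta_in))}

    series_by_id = {s.location_id: s for s in series_list}
    # one joint ensemble so aggregate CIs carry the between-location
    # correlation induced by the shared fixed effects
    ensemble = stage2.sample_curve_ensemble(meta, meta_in, config.n_sim,
                                            np.random.SeedSequence(config.seed))

    mmts: dict[str, attr.MmtResult] = {}
    attributions: dict[str, attr.AttributionResult] = {}
    for idx, (loc, fit) in enumerate(fits.items()):
        curve = blup_curves[loc]
        m = attr.find_mmt(curve, fit.percentile_table)
        if m.at_boundary:
            logger.warning("%s: minimum mortality percentile at boundary (%d)",
                           loc, m.mmp)
        mmts[loc] = m
        attributions[loc] = attr.summarize_attribution(
            series_by_id[loc], curve, m.mmt, fit.percentile_table,
            max_lag=config.max_lag, n_sim=config.n_sim, seed=config.seed,
            coef_draws=ensemble[idx])
    country = attr.aggregate_attribution(list(attributions.values()))

    return ResultBundle(config=config, fits=fits, failed=failed, meta=meta,
                        blups=blups, mmt=mmts, attribution=attributions,
                        country=country)


SENSITIVITY_AXES = ("max_lag", "seasonal_df_per_year", "use_pm25", "period")


def sensitivity_grid(series_list: list[DailySeries],
                     covariates: pd.DataFrame | None,
                     base: RunConfig,
                     axes: dict[str, list]) -> pd.DataFrame:
    """Cartesian product of modelling choices; one full run per cell.

    Failures in a cell are recorded (column `error`) and the grid
    continues.  Returns one row per cell with the country-level
    total/cold/heat attributable fractions.
    """
    for name in axes:
        if name not in SENSITIVITY_AXES:
            raise ValueError(f"unknown sensitivity axis {name!r}; "
                             f"allowed: {SENSITIVITY_AXES}")
    if "use_pm25" in axes and any(axes["use_pm25"]):
        missing = [s.location_id for s in series_list if s.pm25 is None]
        if missing:
            raise ValueError(f"pm25 axis requested but column 'pm25' is "
                             f"missing for locations {missing}")

    names = list(axes.keys())
    rows = []
    for combo in itertools.product(*(axes[n] for n in names)):
        settings = dict(zip(names, combo))
        row = dict(settings)
        try:
            cfg = replace(base, **settings)
            bundle = run_two_stage(series_list, covariates, cfg)
            for c in ("total", "cold", "heat"):
                row[f"af_{c}"] = bundle.country.af[c]
                row[f"af_{c}_lo"], row[f"af_{c}_hi"] = bundle.country.af_ci[c]
            row["error"] = ""
        except Exception as e:            # noqa: BLE001 - per-cell isolation
            row["error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)
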
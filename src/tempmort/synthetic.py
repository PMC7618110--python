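"""Synthetic multi-location daily mortality with a known risk surface.

Every pipeline stage needs a recoverable target, so the generator
produces, for k locations over a span of years:

* a daily mean temperature series: seasonal sinusoid (weak amplitude,
  as near the equator) plus AR(1) Gaussian noise;
* a daily relative-humidity series (AR(1) around a location mean);
* daily death counts with log-mean = seasonal/trend baseline +
  day-of-week effects + the true exposure-lag-response contribution,
  drawn negative-binomial to realize a target quasi-Poisson
  dispersion phi (phi = 1 reduces to Poisson);
* a location-covariate table shaped like the study's meta-predictors;
* the exact truth (curves, MMT/MMP, attributable fractions) computed
  by direct arithmetic on the generated exposure history, never
  through the fitting code.

The true overall cumulative curve is piecewise quadratic in
temperature with a single minimum at a chosen percentile of the
location's own temperature distribution, giving the J- or U-shapes
typical of tropical-setting studies: a heat limb scaled to a chosen
log-RR at the 99th percentile and a cold limb scaled at the 1st.
Each limb carries its own normalized lag-weight profile, so scenarios
can make heat acute and cold slowly-emerging.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import math

import numpy as np
import pandas as pd
import yaml

from .stage1 import PERCENTILE_GRID, DailySeries

__all__ = [
    "ClimateParams",
    "BaselineParams",
    "RiskParams",
    "MetaStructure",
    "SimScenario",
    "LocationTruth",
    "SimTruth",
    "SimulatedStudy",
    "lag_weights",
    "simulate_temperature",
    "simulate_deaths",
    "simulate_scenario",
    "paper_like_scenario",
    "true_eta",
]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ClimateParams:
    """Per-location daily temperature process (degrees C)."""

    mean: float
    amplitude: float = 1.5       # seasonal half-range; weak near the equator
    ar: float = 0.7              # day-to-day AR(1) coefficient
    sd: float = 1.5              # stationary marginal standard deviation
    phase: float = 15.0          # day-of-year of the seasonal maximum

    def __post_init__(self) -> None:
        if abs(self.ar) >= 1:
            raise ValueError(f"AR(1) coefficient {self.ar} is non-stationary")
        if self.sd < 0 or self.amplitude < 0:
            raise ValueError("amplitude and sd must be non-negative")


@dataclass(frozen=True)
class BaselineParams:
    """Baseline (temperature-free) mortality process."""

    log_rate: float = math.log(20.0)      # log mean daily deaths
    trend: float = 0.05                 # total log change across the study span
    seasonal_amplitude: float = 0.03    # log-scale seasonal modulation
    dow: tuple[float, ...] = (0.0, -0.01, -0.01, 0.0, 0.01, 0.03, 0.02)


@dataclass(frozen=True)
class RiskParams:
    """True exposure-lag-response surface, percentile-anchored."""

    mmt_percentile: int = 25
    log_rr_heat: float = 0.12    # overall cumulative log-RR at the 99th pct
    log_rr_cold: float = 0.04    # overall cumulative log-RR at the 1st pct
    heat_lag_shape: str = "uniform"
    cold_lag_shape: str = "uniform"
    heat_max_lag: int = 7
    cold_max_lag: int = 7


@dataclass(frozen=True)
class MetaStructure:
    """Between-location variation of the risk surface.

    `modifier_heat` multiplies the heat log-RR by exp(coef * z) where z
    is the named covariate standardized across locations; log-normal
    location deviations with the given sds act on both limbs.
    """

    modifier_heat: tuple[str, float] | None = None
    sd_log_heat: float = 0.0
    sd_log_cold: float = 0.0


@dataclass(frozen=True)
class SimScenario:
    n_locations: int = 32
    years: float = 10.0
    start_date: str = "2010-01-01"
    mean_temp_range: tuple[float, float] = (12.4, 28.2)
    climate: ClimateParams = ClimateParams(mean=20.0)
    baseline: BaselineParams = BaselineParams()
    # spans hamlet-sized to metropolitan departments; the default range
    # integrates to ~2.5M deaths over 32 locations x 10 years
    log_rate_range: tuple[float, float] = (math.log(3.0), math.log(70.0))
    risk: RiskParams = RiskParams()
    meta: MetaStructure = MetaStructure()
    dispersion: float = 1.3
    seed: int = 0

    @property
    def n_days(self) -> int:
        return int(round(self.years * _DAYS_PER_YEAR))

    # -- plain-text (YAML) serialization --------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimScenario":
        d = yaml.safe_load(text)
        d["climate"] = ClimateParams(**{k: _tup(v) for k, v in d["climate"].items()})
        d["baseline"] = BaselineParams(**{k: _tup(v) for k, v in d["baseline"].items()})
        d["risk"] = RiskParams(**d["risk"])
        d["meta"] = MetaStructure(**{k: _tup(v) for k, v in d["meta"].items()})
        for key in ("mean_temp_range", "log_rate_range"):
            d[key] = _tup(d[key])
        return cls(**d)


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass
class LocationTruth:
    location_id: str
    mmt: float
    mmp: int
    percentile_table: np.ndarray
    curve_on_grid: np.ndarray           # overall cumulative log-RR at pcts 1..99
    af: dict[str, float]                # total/cold/heat, percent of deaths
    an: dict[str, float]
    total_deaths: float
    expected_deaths: float


@dataclass
class SimTruth:
    locations: dict[str, LocationTruth]

    def country_af(self) -> dict[str, float]:
        an = {c: sum(t.an[c] for t in self.locations.values()) for c in ("total", "cold", "heat")}
        deaths = sum(t.total_deaths for t in self.locations.values())
        return {c: 100.0 * an[c] / deaths for c in an}


@dataclass
class SimulatedStudy:
    scenario: SimScenario
    series: list[DailySeries]
    covariates: pd.DataFrame
    truth: SimTruth


def lag_weights(shape: str, max_lag: int) -> np.ndarray:
    """Normalized lag-weight profile over lags 0..max_lag.

    uniform: flat; acute: exponential decay (half-life ~1.4 days);
    persistent: gamma-shaped, near zero at lag 0, peaking around lag
    max_lag/3 -- the slow-emerging profile typical of cold effects.
    """
    l = np.arange(max_lag + 1, dtype=float)
    if shape == "uniform":
        w = np.ones_like(l)
    elif shape == "acute":
        w = np.exp(-l / 2.0)
    elif shape == "persistent":
        scale = max(max_lag / 6.0, 1.0)
        w = (l / scale) ** 2 * np.exp(-l / scale)
    else:
        raise ValueError(f"unknown lag shape {shape!r}")
    return w / w.sum()


def simulate_temperature(climate: ClimateParams, n_days: int, seed) -> np.ndarray:
    """Seasonal sinusoid plus stationary AR(1) noise; deterministic
    given the seed."""
    rng = np.random.default_rng(seed)
    day = np.arange(n_days, dtype=float)
    seasonal = climate.amplitude * np.cos(2 * np.pi * (day - climate.phase) / _DAYS_PER_YEAR)
    innov_sd = climate.sd * np.sqrt(1.0 - climate.ar ** 2)
    eps = rng.normal(0.0, 1.0, n_days)
    noise = np.empty(n_days)
    prev = rng.normal(0.0, 1.0) * climate.sd
    for t in range(n_days):
        prev = climate.ar * prev + innov_sd * eps[t]
        noise[t] = prev
    return climate.mean + seasonal + noise


def _piecewise_risk(x: np.ndarray, mmt: float, t1: float, t99: float,
                    log_rr_heat: float, log_rr_cold: float):
    """(heat limb, cold limb) of the true overall cumulative log-RR."""
    x = np.asarray(x, dtype=float)
    heat = np.where(x > mmt, log_rr_heat * ((x - mmt) / max(t99 - mmt, 1e-9)) ** 2, 0.0)
    cold = np.where(x < mmt, log_rr_cold * ((mmt - x) / max(mmt - t1, 1e-9)) ** 2, 0.0)
    return heat, cold


def true_eta(tmean: np.ndarray, mmt: float, t1: float, t99: float,
             log_rr_heat: float, log_rr_cold: float,
             w_heat: np.ndarray, w_cold: np.ndarray) -> np.ndarray:
    """Daily cumulative log-RR contribution of the exposure history.

    eta_t = sum_l w_heat[l] * fh(x_{t-l}) + w_cold[l] * fc(x_{t-l});
    days whose history extends before the series start get NaN.
    """
    tmean = np.asarray(tmean, dtype=float)
    n = tmean.size
    fh, fc = _piecewise_risk(tmean, mmt, t1, t99, log_rr_heat, log_rr_cold)
    eta = np.zeros(n)
    maxl = max(len(w_heat), len(w_cold)) - 1
    for l, w in enumerate(w_heat):
        shifted = np.full(n, np.nan)
        shifted[l:] = fh[:n - l] if l else fh
        eta = eta + w * shifted if l else eta + w * fh
    for l, w in enumerate(w_cold):
        shifted = np.full(n, np.nan)
        shifted[l:] = fc[:n - l] if l else fc
        eta = eta + w * shifted if l else eta + w * fc
    eta[:maxl] = np.nan
    return eta


def simulate_deaths(mu: np.ndarray, dispersion: float, seed) -> np.ndarray:
    """Counts with mean mu and variance phi * mu.

    Realized as a gamma-Poisson mixture with day-specific shape
    mu/(phi-1), which gives Var = mu * phi exactly; phi = 1 is plain
    Poisson.  Quasi-Poisson has no generative form, so this is the
    standard stand-in.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu > 1e7):
        raise FloatingPointError("expected counts overflow plausibility")
    rng = np.random.default_rng(seed)
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    if dispersion == 1.0:
        return rng.poisson(mu).astype(float)
    theta = mu / (dispersion - 1.0)
    lam = rng.gamma(shape=theta, scale=(dispersion - 1.0))
    return rng.poisson(lam).astype(float)


def _location_mu(dates: pd.DatetimeIndex, eta: np.ndarray,
                 baseline: BaselineParams) -> np.ndarray:
    n = len(dates)
    day = np.arange(n, dtype=float)
    doy = dates.dayofyear.to_numpy(dtype=float)
    log_mu = (baseline.log_rate
              + baseline.trend * day / max(n - 1, 1)
              + baseline.seasonal_amplitude * np.cos(2 * np.pi * doy / _DAYS_PER_YEAR)
              + np.asarray(baseline.dow)[dates.dayofweek.to_numpy()]
              + np.where(np.isfinite(eta), eta, 0.0))
    return np.exp(log_mu)


def simulate_scenario(scenario: SimScenario) -> SimulatedStudy:
    """Generate the full multi-location study plus its truth."""
    k = scenario.n_locations
    n = scenario.n_days
    root = np.random.SeedSequence(scenario.seed)
    loc_seeds = root.spawn(k)
    rng = np.random.default_rng(root.spawn(1)[0])

    # location-level draws (once per scenario)
    means = np.linspace(*scenario.mean_temp_range, k) if k > 1 else \
        np.array([np.mean(scenario.mean_temp_range)])
    log_rates = rng.uniform(*scenario.log_rate_range, size=k)
    latitudes = rng.uniform(-4.0, 12.0, size=k)
    # elevation anti-correlates with temperature (lapse rate ~6.5 K/km)
    elevations = np.maximum((scenario.mean_temp_range[1] + 0.5 - means) / 0.0065
                            + rng.normal(0.0, 150.0, size=k), 0.0)
    pop_density = np.exp(rng.uniform(np.log(1.0), np.log(300.0), size=k))
    mpi = rng.uniform(5.0, 60.0, size=k)
    rh_means = rng.uniform(65.0, 90.0, size=k)

    z_elev = (elevations - elevations.mean()) / max(elevations.std(), 1e-12)
    dev_heat = rng.normal(0.0, scenario.meta.sd_log_heat, size=k)
    dev_cold = rng.normal(0.0, scenario.meta.sd_log_cold, size=k)

    w_heat = lag_weights(scenario.risk.heat_lag_shape, scenario.risk.heat_max_lag)
    w_cold = lag_weights(scenario.risk.cold_lag_shape, scenario.risk.cold_max_lag)
    burn = max(len(w_heat), len(w_cold)) - 1

    dates = pd.date_range(scenario.start_date, periods=n, freq="D")
    series: list[DailySeries] = []
    truths: dict[str, LocationTruth] = {}
    rows = []

    for i in range(k):
        loc = f"L{i:02d}"
        sub = loc_seeds[i].spawn(4)
        climate = replace(scenario.climate, mean=float(means[i]))
        temp_full = simulate_temperature(climate, n + burn, sub[0])
        tmean = temp_full[burn:]

        pct = np.percentile(tmean, PERCENTILE_GRID, method="linear")
        mmt = float(pct[scenario.risk.mmt_percentile - 1])
        t1, t99 = float(pct[0]), float(pct[98])

        lrh = scenario.risk.log_rr_heat * np.exp(dev_heat[i])
        lrc = scenario.risk.log_rr_cold * np.exp(dev_cold[i])
        if scenario.meta.modifier_heat is not None:
            name, coef = scenario.meta.modifier_heat
            if name != "pw_elevation":
                raise ValueError("only pw_elevation is wired as a heat modifier")
            lrh = lrh * np.exp(coef * z_elev[i])

        eta_full = true_eta(temp_full, mmt, t1, t99, lrh, lrc, w_heat, w_cold)
        eta = eta_full[burn:]
        if not np.all(np.isfinite(eta)):
            raise RuntimeError("burn-in insufficient for truth lag window")

        baseline = replace(scenario.baseline, log_rate=float(log_rates[i]))
        mu = _location_mu(dates, eta, baseline)
        deaths = simulate_deaths(mu, scenario.dispersion, sub[1])

        rh_rng = np.random.default_rng(sub[2])
        rh_noise = np.empty(n)
        prev = rh_rng.normal(0.0, 5.0)
        eps = rh_rng.normal(0.0, 5.0 * np.sqrt(1 - 0.8 ** 2), size=n)
        for t in range(n):
            prev = 0.8 * prev + eps[t]
            rh_noise[t] = prev
        rh = np.clip(rh_means[i] + rh_noise, 20.0, 100.0)

        s = DailySeries(location_id=loc, dates=dates, deaths=deaths,
                        tmean=tmean, rh=rh)
        series.append(s)

        heat_g, cold_g = _piecewise_risk(pct, mmt, t1, t99, lrh, lrc)
        an_t = deaths * (1.0 - np.exp(-eta))
        cold_mask = tmean < mmt
        heat_mask = tmean > mmt
        an = {"total": float(np.sum(an_t[tmean != mmt])),
              "cold": float(np.sum(an_t[cold_mask])),
              "heat": float(np.sum(an_t[heat_mask]))}
        total_deaths = float(deaths.sum())
        truths[loc] = LocationTruth(
            location_id=loc, mmt=mmt, mmp=scenario.risk.mmt_percentile,
            percentile_table=pct, curve_on_grid=heat_g + cold_g,
            an=an, af={c: 100.0 * v / total_deaths for c, v in an.items()},
            total_deaths=total_deaths, expected_deaths=float(mu.sum()))

        rows.append({
            "location_id": loc,
            "avg_temp": float(np.mean(tmean)),
            "temp_range": float(np.max(tmean) - np.min(tmean)),
            "pw_latitude": float(latitudes[i]),
            "pw_elevation": float(elevations[i]),
            "pop_density": float(pop_density[i]),
            "avg_rh": float(np.mean(rh)),
            "mpi": float(mpi[i]),
        })

    covariates = pd.DataFrame(rows).set_index("location_id")
    return SimulatedStudy(scenario=scenario, series=series,
                          covariates=covariates, truth=SimTruth(locations=truths))


def paper_like_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The default study conditions: 32 locations, 10 years of daily
    counts, mean temperatures spanning ~12-28 C, a J-shaped risk
    surface (heat limb twice the cold limb) with acute heat and
    slowly-emerging cold contributions, and mild overdispersion."""
    base = SimScenario(
        n_locations=32,
        years=10.0,
        risk=RiskParams(mmt_percentile=25, log_rr_heat=0.12, log_rr_cold=0.04,
                        heat_lag_shape="acute", heat_max_lag=7,
                        cold_lag_shape="persistent", cold_max_lag=28),
        meta=MetaStructure(modifier_heat=("pw_elevation", -0.15), sd_log_heat=0.2,
                           sd_log_cold=0.2),
        dispersion=1.3,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
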
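"""Per-location quasi-Poisson time-series regression.

The first-stage model regresses daily all-cause death counts on a DLNM
cross-basis of daily mean temperature, controlling for seasonality and
long-term trend (natural cubic spline of the day index with a fixed
number of degrees of freedom per year), day of week (indicator terms,
Monday reference), same-day relative humidity (linear term) and,
optionally, same-day PM2.5 (linear term).

Estimation is iteratively reweighted least squares (IRLS) to the
Poisson maximum likelihood; the quasi-Poisson dispersion phi is the
Pearson chi-square over its residual degrees of freedom and scales the
coefficient covariance.  Point estimates therefore coincide with the
Poisson MLE; only standard errors change.

Curves are fit uncentred; re-centering (at the minimum-mortality
temperature, once known) happens at prediction time since log-RR
differences are invariant to the centering choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisSpec, ncs_spec_from_df, percentile_knots
from .crossbasis import (CrossBasis, CrossBasisSpec, ReducedCurve,
                         build_crossbasis, default_lag_spec, reduce_overall)

__all__ = [
    "DailySeries",
    "ModelConfig",
    "DesignInfo",
    "Stage1Fit",
    "build_design",
    "fit_quasipoisson",
    "fit_location",
    "read_daily_series",
    "write_daily_series",
]

_DAYS_PER_YEAR = 365.25


@dataclass
class DailySeries:
    """One location's daily series on a gapless calendar grid.

    Missing observations are NaN markers, never absent rows.
    """

    location_id: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    tmean: np.ndarray
    rh: np.ndarray | None = None
    pm25: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        n = len(self.dates)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.tmean = np.asarray(self.tmean, dtype=float)
        for name in ("deaths", "tmean"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of dates")
        for name in ("rh", "pm25"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValueError(f"{name} length != number of dates")
                setattr(self, name, v)
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas != 1):
                raise ValueError(f"{self.location_id}: dates must be consecutive calendar days")
        obs = self.deaths[np.isfinite(self.deaths)]
        if np.any(obs < 0) or np.any(obs != np.round(obs)):
            raise ValueError("deaths must be non-negative integers (or NaN)")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        return len(self) / _DAYS_PER_YEAR

    def slice_period(self, start, end) -> "DailySeries":
        """Sub-series restricted to [start, end] (inclusive)."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise ValueError("empty period slice")
        return DailySeries(
            location_id=self.location_id,
            dates=self.dates[mask],
            deaths=self.deaths[mask],
            tmean=self.tmean[mask],
            rh=None if self.rh is None else self.rh[mask],
            pm25=None if self.pm25 is None else self.pm25[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"location_id": self.location_id, "date": self.dates.strftime("%Y-%m-%d"),
             "deaths": self.deaths, "tmean": self.tmean}
        if self.rh is not None:
            d["rh"] = self.rh
        if self.pm25 is not None:
            d["pm25"] = self.pm25
        return pd.DataFrame(d)


def write_daily_series(series_list, path) -> None:
    """Long-format delimited file with a location column."""
    pd.concat([s.to_frame() for s in series_list]).to_csv(path, sep="\t", index=False)


def read_daily_series(path) -> list[DailySeries]:
    df = pd.read_csv(path, sep="\t", dtype={"location_id": str})
    out = []
    for loc, g in df.groupby("location_id", sort=True):
        out.append(DailySeries(
            location_id=str(loc),
            dates=pd.DatetimeIndex(pd.to_datetime(g["date"])),
            deaths=g["deaths"].to_numpy(),
            tmean=g["tmean"].to_numpy(),
            rh=g["rh"].to_numpy() if "rh" in g else None,
            pm25=g["pm25"].to_numpy() if "pm25" in g else None,
        ))
    return out


@dataclass(frozen=True)
class ModelConfig:
    """First-stage model settings (defaults = the main analysis)."""

    max_lag: int = 7
    var_degree: int = 3
    var_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    lag_knots: int | None = None          # None -> 2 for L<=7, 3 beyond
    seasonal_df_per_year: float = 6.0
    use_rh: bool = True
    use_pm25: bool = False
    dow_reference: int = 0                # Monday

    def lag_spec(self) -> BasisSpec:
        return default_lag_spec(self.max_lag, self.lag_knots)

    def var_spec(self, tmean: np.ndarray) -> BasisSpec:
        """Exposure B-spline with percentile knots on the location's own
        temperature distribution; boundary knots at the observed range."""
        t = np.asarray(tmean, dtype=float)
        t = t[np.isfinite(t)]
        knots = percentile_knots(t, self.var_knot_percentiles)
        return BasisSpec(
            family="bspline",
            degree=self.var_degree,
            interior_knots=tuple(knots),
            boundary_knots=(float(t.min()), float(t.max())),
            with_intercept=False,
        )

    def crossbasis_spec(self, tmean: np.ndarray) -> CrossBasisSpec:
        return CrossBasisSpec(var_spec=self.var_spec(tmean),
                              lag_spec=self.lag_spec(), max_lag=self.max_lag)


@dataclass
class DesignInfo:
    """Design matrix plus the block structure of its columns."""

    X: np.ndarray
    blocks: dict[str, slice]
    crossbasis: CrossBasis
    valid: np.ndarray              # rows usable in the likelihood

    def block(self, name: str) -> np.ndarray:
        return self.X[:, self.blocks[name]]


def build_design(series: DailySeries, config: ModelConfig,
                 crossbasis: CrossBasis | None = None) -> DesignInfo:
    """Assemble the first-stage design matrix.

    Blocks, in order: intercept | crossbasis | seasonality spline |
    day-of-week indicators (reference dropped) | rh | pm25.
    """
    n = len(series)
    if crossbasis is None:
        cb_spec = config.crossbasis_spec(series.tmean)
        crossbasis = build_crossbasis(series.tmean, cb_spec)

    cols: list[np.ndarray] = []
    blocks: dict[str, slice] = {}

    def add(name: str, mat: np.ndarray) -> None:
        mat = np.atleast_2d(mat.T).T if mat.ndim == 1 else mat
        start = sum(c.shape[1] for c in cols)
        blocks[name] = slice(start, start + mat.shape[1])
        cols.append(mat)

    add("intercept", np.ones((n, 1)))
    add("crossbasis", crossbasis.values)

    n_df = int(round(config.seasonal_df_per_year * series.n_years))
    day_index = np.arange(n, dtype=float)
    seas_spec = ncs_spec_from_df(day_index, n_df, with_intercept=False)
    from .basis import natural_cubic_basis
    add("season", natural_cubic_basis(day_index, seas_spec).values)

    dow = series.dates.dayofweek.to_numpy()
    keep = [d for d in range(7) if d != config.dow_reference]
    add("dow", (dow[:, None] == np.array(keep)[None, :]).astype(float))

    if config.use_rh:
        if series.rh is None or not np.isfinite(series.rh).any():
            raise ValueError(f"{series.location_id}: rh requested but missing from data")
        add("rh", series.rh[:, None])
    if config.use_pm25:
        if series.pm25 is None or not np.isfinite(series.pm25).any():
            raise ValueError(f"{series.location_id}: pm25 requested but missing from data")
        add("pm25", series.pm25[:, None])

    X = np.hstack(cols)
    valid = np.all(np.isfinite(X), axis=1) & np.isfinite(series.deaths)
    return DesignInfo(X=X, blocks=blocks, crossbasis=crossbasis, valid=valid)


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class QuasiPoissonFit:
    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    iterations: int
    converged: bool
    deviance_path: list[float] = field(default_factory=list)
    unscaled_vcov: np.ndarray | None = None


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


def fit_quasipoisson(y, X, blocks: dict[str, slice] | None = None,
                     tol: float = 1e-9, max_iter: int = 50) -> QuasiPoissonFit:
    """Quasi-Poisson fit by IRLS (log link).

    Coefficients equal the Poisson MLE; the dispersion phi = Pearson
    chi-square / (n - p) inflates the covariance.  Convergence when the
    largest absolute coefficient update falls below `tol`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in y or X; drop incomplete rows "
                         "before fitting (see DesignInfo.valid)")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"only {n} rows for {p} parameters")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise RankDeficientError(_rank_message(X, blocks))

    # starting values: a damped saturated fit (not itself a model fit,
    # so the deviance path starts at the first IRLS iterate)
    mu = np.maximum((y + np.mean(y)) / 2.0, 1e-8)
    eta = np.log(mu)
    coef = np.zeros(p)
    deviance_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        xw = X * w[:, None]
        xtwx = X.T @ xw
        new = np.linalg.solve(xtwx, xw.T @ z)
        delta = np.max(np.abs(new - coef))
        coef = new
        eta = X @ coef
        if np.max(eta) > 300:
            raise FloatingPointError("linear predictor overflow in IRLS")
        mu = np.exp(eta)
        deviance_path.append(_poisson_deviance(y, mu))
        if delta < tol:
            converged = True
            break

    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - p)
    xtwx = X.T @ (X * mu[:, None])
    unscaled = np.linalg.inv(xtwx)
    return QuasiPoissonFit(coef=coef, vcov=dispersion * unscaled,
                           dispersion=dispersion, iterations=it,
                           converged=converged, deviance_path=deviance_path,
                           unscaled_vcov=unscaled)


def _rank_message(X: np.ndarray, blocks: dict[str, slice] | None) -> str:
    if not blocks:
        return "design matrix is rank deficient"
    # attribute the deficiency to blocks via pivoted-QR column norms
    from scipy.linalg import qr
    _, r, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    bad_cols = piv[d < d.max() * 1e-10 * X.shape[0]] if d.size else piv
    names = sorted({name for name, sl in blocks.items()
                    for c in np.atleast_1d(bad_cols) if sl.start <= c < sl.stop})
    return ("design matrix is rank deficient; offending block(s): "
            + (", ".join(names) if names else "unidentified"))


@dataclass
class Stage1Fit:
    """Everything the second stage and the attribution step need."""

    location_id: str
    coef_full: np.ndarray
    vcov_full: np.ndarray
    dispersion: float
    reduced: ReducedCurve
    cb_spec: CrossBasisSpec
    percentile_table: np.ndarray        # temperature at percentiles 1..99
    n_days_used: int
    converged: bool
    iterations: int
    total_deaths: float


PERCENTILE_GRID = np.arange(1, 100)


def fit_location(series: DailySeries, config: ModelConfig) -> Stage1Fit:
    """Fit the first-stage model for one location and reduce to the
    overall cumulative exposure-response curve."""
    if len(series) - config.max_lag < int(_DAYS_PER_YEAR):
        raise ValueError(f"{series.location_id}: less than one year of data after lag trimming")
    design = build_design(series, config)
    valid = design.valid
    fit = fit_quasipoisson(series.deaths[valid], design.X[valid],
                           blocks=design.blocks)

    sl = design.blocks["crossbasis"]
    coef_cb = fit.coef[sl]
    vcov_cb = fit.vcov[sl, sl]
    reduced = reduce_overall(coef_cb, vcov_cb, design.crossbasis.spec)

    t = series.tmean[np.isfinite(series.tmean)]
    pct = np.percentile(t, PERCENTILE_GRID, method="linear")
    return Stage1Fit(
        location_id=series.location_id,
        coef_full=coef_cb,
        vcov_full=vcov_cb,
        dispersion=fit.dispersion,
        reduced=reduced,
        cb_spec=design.crossbasis.spec,
        percentile_table=pct,
        n_days_used=int(valid.sum()),
        converged=fit.converged,
        iterations=fit.iterations,
        total_deaths=float(np.nansum(series.deaths)),
    )
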
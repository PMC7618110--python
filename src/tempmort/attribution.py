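"""Minimum mortality temperature and attributable burden.

The minimum mortality temperature (MMT) is the arg-min of the pooled
(BLUP) overall cumulative exposure-response curve on the location's
empirical temperature percentile grid (percentiles 1..99); its grid
percentile is the minimum mortality percentile (MMP).  The curve is
then re-centered at the MMT and each day's exposure history converted
into attributable deaths by backward attribution:

    AN_t = deaths_t * (1 - exp(-eta_t)),
    eta_t = (1/(L+1)) * sum_{l=0..L} f(x_{t-l})

where f is the re-centered overall cumulative log relative risk.  The
overall cumulative curve describes the total effect of sustained
exposure over the lag window, so its contribution is apportioned
equally across the L+1 lags; for constant exposure the formula is
exact.  Days with incomplete exposure history contribute zero and are
counted.

Attributable numbers are summed over all days (total), days colder /
warmer than the MMT (cold / heat; days exactly at the MMT belong to
neither and contribute zero), and days beyond the 1st/5th/10th (cold
tail) and 90th/95th/99th (heat tail) temperature percentiles.
Attributable fractions are 100 * AN / total deaths.  Confidence
intervals are empirical 2.5th/97.5th percentiles over Monte-Carlo
redraws of the curve coefficients from their estimated multivariate
normal distribution, re-run through the full attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import evaluate_basis
from .crossbasis import ReducedCurve
from .stage1 import PERCENTILE_GRID, DailySeries

__all__ = [
    "MmtResult",
    "AttributionResult",
    "find_mmt",
    "attributable_series",
    "summarize_attribution",
    "aggregate_attribution",
    "CATEGORIES",
]

CATEGORIES = ("total", "cold", "heat", "p1", "p5", "p10", "p90", "p95", "p99")


@dataclass(frozen=True)
class MmtResult:
    mmt: float
    mmp: int
    at_boundary: bool
    search_grid: np.ndarray


@dataclass
class AttributionResult:
    location_id: str
    an: dict[str, float]
    an_ci: dict[str, tuple[float, float]]
    af: dict[str, float]
    af_ci: dict[str, tuple[float, float]]
    total_deaths: float
    n_incomplete: int
    n_sim: int
    seed: int | None
    an_draws: np.ndarray | None = None      # (n_categories, n_sim), for aggregation

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in CATEGORIES:
            rows.append({
                "category": c,
                "an": self.an[c], "an_lo": self.an_ci[c][0], "an_hi": self.an_ci[c][1],
                "af": self.af[c], "af_lo": self.af_ci[c][0], "af_hi": self.af_ci[c][1],
            })
        df = pd.DataFrame(rows)
        df.insert(0, "location_id", self.location_id)
        return df


def find_mmt(curve: ReducedCurve, percentile_table: np.ndarray) -> MmtResult:
    """Arg-min of the (un-centered) curve over the percentile grid.

    Ties are broken toward the median percentile.  A minimum at
    percentile 1 or 99 signals a monotone curve over the observed
    range and is flagged.
    """
    grid = np.asarray(percentile_table, dtype=float)
    if grid.size != PERCENTILE_GRID.size:
        raise ValueError(f"percentile table must cover percentiles 1..99 "
                         f"({PERCENTILE_GRID.size} values), got {grid.size}")
    vals = evaluate_basis(grid, curve.spec).values @ curve.coef
    lo = np.min(vals)
    ties = np.where(vals <= lo + 1e-12 * max(abs(lo), 1.0))[0]
    best = ties[np.argmin(np.abs(PERCENTILE_GRID[ties] - 50))]
    mmp = int(PERCENTILE_GRID[best])
    return MmtResult(mmt=float(grid[best]), mmp=mmp,
                     at_boundary=(mmp in (1, 99)), search_grid=grid)


def _lag_averaged_basis(tmean: np.ndarray, curve: ReducedCurve, max_lag: int):
    """Per-day design rows (1/(L+1)) sum_l b(x_{t-l}) and the mask of
    days with complete, fully-observed history."""
    n = tmean.size
    finite = np.isfinite(tmean)
    B = np.full((n, curve.coef.size), np.nan)
    if finite.any():
        spec = curve.spec
        x = tmean[finite]
        if spec.family == "bspline" and not spec.clamp:
            from dataclasses import replace
            spec = replace(spec, clamp=True)
        B[finite] = evaluate_basis(x, spec).values
    acc = np.zeros_like(B)
    for l in range(max_lag + 1):
        shifted = np.full_like(B, np.nan)
        shifted[l:] = B[:n - l] if l else B
        acc += shifted
    acc /= (max_lag + 1)
    complete = np.all(np.isfinite(acc), axis=1)
    return acc, complete


def attributable_series(series: DailySeries, curve: ReducedCurve, mmt: float,
                        max_lag: int) -> np.ndarray:
    """Daily attributable deaths under backward attribution.

    Days with incomplete exposure history or missing deaths contribute
    exactly zero.  Negative values arise on the protective side of the
    curve and are retained.
    """
    lo, hi = curve.spec.boundary_knots
    if not (lo <= mmt <= hi):
        raise ValueError(f"mmt {mmt} outside curve domain [{lo}, {hi}]")
    Bbar, complete = _lag_averaged_basis(series.tmean, curve, max_lag)
    b0 = evaluate_basis(np.array([mmt]), curve.spec).values[0]
    eta = np.where(complete, (Bbar - b0) @ curve.coef, 0.0)
    deaths = np.where(np.isfinite(series.deaths), series.deaths, 0.0)
    usable = _usable_days(series, complete, mmt)
    an = np.where(usable, deaths * (1.0 - np.exp(-eta)), 0.0)
    return an


def _usable_days(series: DailySeries, complete: np.ndarray, mmt: float) -> np.ndarray:
    """Days entering the attribution sums: complete history, observed
    deaths, and a mean temperature distinct from the MMT (days exactly
    at the MMT belong to neither the cold nor the heat side and are
    zeroed so that total = cold + heat holds exactly)."""
    with np.errstate(invalid="ignore"):
        off_mmt = series.tmean != mmt
    return complete & np.isfinite(series.deaths) & off_mmt


def _category_masks(tmean: np.ndarray, mmt: float,
                    percentile_table: np.ndarray) -> dict[str, np.ndarray]:
    t = tmean
    pct = {p: percentile_table[p - 1] for p in (1, 5, 10, 90, 95, 99)}
    with np.errstate(invalid="ignore"):
        return {
            "total": np.ones_like(t, dtype=bool),
            "cold": t < mmt,
            "heat": t > mmt,
            "p1": t < pct[1],
            "p5": t < pct[5],
            "p10": t < pct[10],
            "p90": t > pct[90],
            "p95": t > pct[95],
            "p99": t > pct[99],
        }


def summarize_attribution(series: DailySeries, curve: ReducedCurve, mmt: float,
                          percentile_table: np.ndarray, max_lag: int,
                          n_sim: int = 1000, seed: int | None = None,
                          keep_draws: bool = True,
                          mmt_per_draw: bool = False,
                          coef_draws: np.ndarray | None = None) -> AttributionResult:
    """Point estimates and empirical Monte-Carlo confidence intervals
    for attributable numbers and fractions by category.

    By default every redraw is centered at the point-estimate MMT, the
    convention of backward-attribution software in this field.  With
    ``mmt_per_draw`` each redraw instead locates its own curve minimum
    and centers there, carrying MMT uncertainty into the intervals;
    because the minimum of a noisier redraw is more downward-biased
    than the point estimate's, this shifts the whole interval upward
    and is not the default.

    ``coef_draws`` (n_sim, q) supplies an externally sampled
    coefficient ensemble — used by the pipeline so that draws share
    their fixed-effect component across locations and aggregate
    intervals carry the between-location correlation.  When absent,
    draws come from N(coef, vcov) of this curve alone.
    """
    import warnings
    if coef_draws is not None:
        n_sim = int(coef_draws.shape[0])
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is small; empirical CIs will be unstable")
    if seed is None and coef_draws is None:
        raise ValueError("a seed is required for the Monte-Carlo CIs")

    Bbar, complete = _lag_averaged_basis(series.tmean, curve, max_lag)
    b0 = evaluate_basis(np.array([mmt]), curve.spec).values[0]
    X = Bbar - b0
    usable = _usable_days(series, complete, mmt)
    deaths = np.where(np.isfinite(series.deaths), series.deaths, 0.0)
    total_deaths = float(deaths.sum())
    masks = _category_masks(series.tmean, mmt, percentile_table)

    def category_sums(an_daily: np.ndarray) -> np.ndarray:
        return np.array([np.sum(an_daily[m & usable]) for m in masks.values()])

    eta = X[usable] @ curve.coef
    an_daily = np.zeros(len(series))
    an_daily[usable] = deaths[usable] * (1.0 - np.exp(-eta))
    point = category_sums(an_daily)

    if coef_draws is not None:
        draws = np.asarray(coef_draws, dtype=float)
    else:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(curve.coef, curve.vcov, size=n_sim,
                                        method="svd")             # (n_sim, q)
    if mmt_per_draw:
        cat_draws = _draws_with_own_mmt(series, curve, draws, Bbar, complete,
                                        deaths, percentile_table)
    else:
        eta_d = X[usable] @ draws.T                                # (n_use, n_sim)
        an_d = deaths[usable, None] * (1.0 - np.exp(-eta_d))
        cat_draws = np.stack([an_d[m[usable]].sum(axis=0) for m in masks.values()])

    lo, hi = np.percentile(cat_draws, [2.5, 97.5], axis=1)
    names = list(masks.keys())
    an = dict(zip(names, point))
    an_ci = {c: (float(lo[i]), float(hi[i])) for i, c in enumerate(names)}
    af = {c: 100.0 * an[c] / total_deaths for c in names}
    af_ci = {c: (100.0 * an_ci[c][0] / total_deaths, 100.0 * an_ci[c][1] / total_deaths)
             for c in names}
    return AttributionResult(
        location_id=series.location_id, an=an, an_ci=an_ci, af=af, af_ci=af_ci,
        total_deaths=total_deaths, n_incomplete=int((~usable).sum()),
        n_sim=n_sim, seed=seed,
        an_draws=cat_draws if keep_draws else None)


def _draws_with_own_mmt(series: DailySeries, curve: ReducedCurve,
                        draws: np.ndarray, Bbar: np.ndarray,
                        complete: np.ndarray, deaths: np.ndarray,
                        percentile_table: np.ndarray) -> np.ndarray:
    """Category sums per draw, each draw centered at its own curve
    minimum (the full attribution chain re-run per redraw)."""
    grid = np.asarray(percentile_table, dtype=float)
    Bgrid = evaluate_basis(grid, curve.spec).values          # (99, q)
    curve_d = Bgrid @ draws.T                                # (99, n_sim)
    amin = np.argmin(curve_d, axis=0)
    mmt_d = grid[amin]                                       # (n_sim,)
    offset = np.take_along_axis(curve_d, amin[None, :], axis=0)[0]

    obs = np.isfinite(series.deaths)
    eta_d = Bbar @ draws.T - offset[None, :]                 # (n, n_sim)
    eta_d = np.where((complete & obs)[:, None], eta_d, 0.0)
    with np.errstate(invalid="ignore"):
        off_mmt = series.tmean[:, None] != mmt_d[None, :]    # (n, n_sim)
    an_d = deaths[:, None] * (1.0 - np.exp(-eta_d)) * off_mmt

    t = series.tmean
    pct = {p: grid[p - 1] for p in (1, 5, 10, 90, 95, 99)}
    with np.errstate(invalid="ignore"):
        cold = t[:, None] < mmt_d[None, :]
        heat = t[:, None] > mmt_d[None, :]
        fixed = {p: (t < pct[p]) if p < 50 else (t > pct[p])
                 for p in (1, 5, 10, 90, 95, 99)}
    out = np.empty((len(CATEGORIES), draws.shape[0]))
    out[0] = an_d.sum(axis=0)
    out[1] = (an_d * cold).sum(axis=0)
    out[2] = (an_d * heat).sum(axis=0)
    for i, p in enumerate((1, 5, 10, 90, 95, 99), start=3):
        out[i] = an_d[fixed[p]].sum(axis=0)
    return out


def aggregate_attribution(results: list[AttributionResult],
                          location_id: str = "ALL") -> AttributionResult:
    """Country-level aggregate: attributable numbers sum across
    locations (draw-wise for the CIs); fractions use summed deaths."""
    if not results:
        raise ValueError("nothing to aggregate")
    if any(r.an_draws is None for r in results):
        raise ValueError("per-location draws required for aggregation")
    n_sim = {r.n_sim for r in results}
    if len(n_sim) != 1:
        raise ValueError("all locations must use the same n_sim")
    total_deaths = float(sum(r.total_deaths for r in results))
    an = {c: float(sum(r.an[c] for r in results)) for c in CATEGORIES}
    draws = np.sum([r.an_draws for r in results], axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=1)
    an_ci = {c: (float(lo[i]), float(hi[i])) for i, c in enumerate(CATEGORIES)}
    af = {c: 100.0 * an[c] / total_deaths for c in CATEGORIES}
    af_ci = {c: (100.0 * an_ci[c][0] / total_deaths, 100.0 * an_ci[c][1] / total_deaths)
             for c in CATEGORIES}
    return AttributionResult(
        location_id=location_id, an=an, an_ci=an_ci, af=af, af_ci=af_ci,
        total_deaths=total_deaths,
        n_incomplete=sum(r.n_incomplete for r in results),
        n_sim=n_sim.pop(), seed=results[0].seed, an_draws=draws)
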
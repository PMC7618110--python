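"""Analysis-ready daily series from hourly temperature/dewpoint data.

Relative humidity is derived pointwise from 2 m temperature and
dewpoint via the August-Roche-Magnus saturation-vapor-pressure
approximation and then averaged to daily means; daily calendar days
are defined in a fixed UTC offset (UTC-5 by default).  Averaging the
hourly RH (rather than applying the formula to daily-mean t/td)
matters because the formula is convex in its arguments; both routes
are exposed so the gap can be inspected.

Gridded-reanalysis ingestion (spatial averaging of ERA5/CAMS fields
over administrative polygons) is out of scope; `read_hourly` documents
the pre-extracted long-format file this module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MAGNUS_A",
    "MAGNUS_B",
    "HourlySeries",
    "rh_magnus",
    "daily_aggregate",
    "hourly_to_daily",
    "read_hourly",
]

# A common August-Roche-Magnus parameterization (a dimensionless, b in
# degrees Celsius); configurable because several published constant
# sets are in circulation.
MAGNUS_A = 17.625
MAGNUS_B = 243.04


@dataclass
class HourlySeries:
    """Hourly 2 m temperature and dewpoint, timestamps in UTC."""

    timestamps: pd.DatetimeIndex
    t2m: np.ndarray
    d2m: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.t2m = np.asarray(self.t2m, dtype=float)
        self.d2m = np.asarray(self.d2m, dtype=float)
        if not (len(self.timestamps) == len(self.t2m) == len(self.d2m)):
            raise ValueError("timestamps/t2m/d2m length mismatch")

    def supersaturated(self) -> np.ndarray:
        """Hours where dewpoint exceeds temperature (physically suspect;
        flagged, not fatal)."""
        with np.errstate(invalid="ignore"):
            return self.d2m > self.t2m


def rh_magnus(t, td, a: float = MAGNUS_A, b: float = MAGNUS_B) -> np.ndarray:
    """Relative humidity (%) from temperature and dewpoint (degrees C).

    RH = 100 * e_s(td) / e_s(t) with e_s(x) proportional to
    exp(a x / (b + x)), clipped to [0, 100].  NaN inputs give NaN.
    """
    t = np.asarray(t, dtype=float)
    td = np.asarray(td, dtype=float)
    finite = np.isfinite(t) & np.isfinite(td)
    if np.any((t[np.isfinite(t)] <= -b)) or np.any((td[np.isfinite(td)] <= -b)):
        raise ValueError(f"temperature at or below -{b} C: Magnus formula singular")
    with np.errstate(invalid="ignore"):
        rh = 100.0 * np.exp(a * td / (b + td) - a * t / (b + t))
    out = np.where(finite, np.clip(rh, 0.0, 100.0), np.nan)
    return out if out.ndim else float(out)


def daily_aggregate(timestamps: pd.DatetimeIndex, values: np.ndarray,
                    utc_offset: float = -5.0,
                    min_coverage: float = 0.75) -> pd.Series:
    """Daily means over calendar days in the shifted time zone.

    The local day of a sample is the calendar date of (timestamp +
    utc_offset hours).  Days observing fewer than `min_coverage` of
    the expected samples (expected count inferred from the sampling
    cadence) are set to NaN.  Already-daily input passes through
    unchanged (idempotent).
    """
    timestamps = pd.DatetimeIndex(timestamps)
    if len(timestamps) == 0:
        raise ValueError("empty input range")
    values = np.asarray(values, dtype=float)
    local = timestamps + pd.Timedelta(hours=utc_offset)
    day = local.normalize()
    s = pd.Series(values, index=day)
    grouped = s.groupby(level=0)
    means = grouped.mean()          # skips NaN within a day
    counts = grouped.apply(lambda g: int(np.isfinite(g.to_numpy()).sum()))

    if len(timestamps) > 1:
        step = np.min(np.diff(timestamps.values)).astype("timedelta64[s]").astype(float)
        expected = max(1, int(round(86400.0 / step))) if step > 0 else 1
    else:
        expected = 1
    means[counts < min_coverage * expected] = np.nan
    means.index.name = "date"
    return means


def hourly_to_daily(hourly: HourlySeries, utc_offset: float = -5.0,
                    a: float = MAGNUS_A, b: float = MAGNUS_B) -> pd.DataFrame:
    """Daily mean temperature and relative humidity.

    RH is computed hour by hour and then averaged (mean-of-RH, not
    RH-of-means).
    """
    rh = rh_magnus(hourly.t2m, hourly.d2m, a=a, b=b)
    tmean = daily_aggregate(hourly.timestamps, hourly.t2m, utc_offset)
    rhmean = daily_aggregate(hourly.timestamps, rh, utc_offset)
    return pd.DataFrame({"tmean": tmean, "rh": rhmean})


def read_hourly(path) -> HourlySeries:
    """Read a pre-extracted long-format hourly file.

    Expected tab-delimited columns: `timestamp` (ISO 8601, UTC),
    `t2m` and `d2m` (degrees Celsius), one row per hour, already
    spatially averaged over the location of interest.
    """
    df = pd.read_csv(path, sep="\t")
    return HourlySeries(
        timestamps=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
        t2m=df["t2m"].to_numpy(),
        d2m=df["d2m"].to_numpy(),
    )
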
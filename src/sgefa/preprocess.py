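"""Preprocessing of monthly climate fields and regional series.

The feedback estimator operates on deseasonalized, detrended anomalies.
This module removes the mean seasonal cycle and the long-term linear trend,
extracts ocean basins (handling dateline-wrapping boxes), computes
cosine-latitude-weighted regional means, and pools observations into
overlapping three-month seasons with the forcing lagged by ``tau`` months.

Gridded fields are :class:`xarray.DataArray` objects with dimensions
``(time, lat, lon)`` and a monthly time axis; regional series are
:class:`pandas.Series` with a monthly :class:`pandas.PeriodIndex`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "BasinSpec",
    "SeasonWindow",
    "PooledSamples",
    "DEFAULT_BASINS",
    "season_window",
    "monthly_anomalies",
    "detrend_linear",
    "anomalize",
    "extract_basin",
    "regional_mean",
    "pool_season",
]


@dataclass(frozen=True)
class BasinSpec:
    """Rectangular ocean basin in degrees; ``lon_min > lon_max`` wraps the dateline."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ValueError(f"basin {self.name}: invalid latitude bounds")


#: The eight canonical SST basins (degrees; longitudes east-positive).
DEFAULT_BASINS: tuple[BasinSpec, ...] = (
    BasinSpec("TP", -20, 20, 120, -60),   # tropical Pacific, wraps dateline
    BasinSpec("TA", -20, 20, -70, 20),    # tropical Atlantic
    BasinSpec("TI", -20, 20, 35, 105),    # tropical Indian
    BasinSpec("NP", 20, 60, 120, -100),   # North Pacific, wraps dateline
    BasinSpec("NA", 20, 60, -90, -10),    # North Atlantic
    BasinSpec("SP", -60, -20, 150, -70),  # South Pacific, wraps dateline
    BasinSpec("SA", -60, -20, -70, 20),   # South Atlantic
    BasinSpec("SI", -60, -20, 20, 120),   # South Indian
)


@dataclass(frozen=True)
class SeasonWindow:
    """Three consecutive calendar months; index 1 = Jan-Feb-Mar, 12 wraps to Feb."""

    index: int
    months: tuple[int, int, int]


def season_window(index: int) -> SeasonWindow:
    if not 1 <= index <= 12:
        raise ValueError("season index must be in 1..12")
    months = tuple((index - 1 + k) % 12 + 1 for k in range(3))
    return SeasonWindow(index, months)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# anomalies and detrending


def _require_two_years(n_months: int) -> None:
    if n_months < 24:
        raise ValueError(
            f"need at least 2 full years (24 months) of data, got {n_months}"
        )


def monthly_anomalies(x: xr.DataArray | pd.Series):
    """Remove the mean seasonal cycle (per-calendar-month climatology).

    Output per-calendar-month means are zero to numerical precision; missing
    values propagate. Idempotent.
    """
    if isinstance(x, xr.DataArray):
        _require_two_years(x.sizes["time"])
        clim = x.groupby("time.month").mean("time")
        out = (x.groupby("time.month") - clim).drop_vars("month")
        out.attrs = dict(x.attrs)
        return out
    _require_two_years(len(x))
    months = x.index.month
    clim = x.groupby(months).transform("mean")
    return x - clim


def detrend_linear(x: xr.DataArray | pd.Series):
    """Remove the least-squares linear trend in the month index.

    Fitted independently per grid cell for fields. NaNs are excluded from the
    fit and propagate to the output. Idempotent.
    """
    if isinstance(x, xr.DataArray):
        vals = x.values.astype(float)
        nt = vals.shape[0]
        t = np.arange(nt, dtype=float)
        flat = vals.reshape(nt, -1)
        out = np.full_like(flat, np.nan)
        for j in range(flat.shape[1]):
            col = flat[:, j]
            ok = np.isfinite(col)
            if ok.sum() < 2:
                continue
            b, a = np.polyfit(t[ok], col[ok], 1)
            out[ok, j] = col[ok] - (a + b * t[ok])
        res = x.copy(data=out.reshape(vals.shape))
        return res
    vals = np.asarray(x, dtype=float)
    t = np.arange(len(vals), dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("series has fewer than 2 finite values")
    b, a = np.polyfit(t[ok], vals[ok], 1)
    return x - (a + b * t)


def anomalize(x):
    """Seasonal cycle then linear trend removal — the estimator's required input."""
    return detrend_linear(monthly_anomalies(x))


# ---------------------------------------------------------------------------
# spatial operations


def _lon360(lon):
    return np.mod(np.asarray(lon, dtype=float), 360.0)


def extract_basin(field: xr.DataArray, basin: BasinSpec) -> xr.DataArray:
    """Select the cells inside a basin box.

    Longitudes are compared in [0, 360) internally so boxes spanning the
    dateline (e.g. 120E-60W) select one contiguous logical region; the
    output keeps the input's longitude convention, rolled so the box is
    contiguous along the lon axis.
    """
    lat = field["lat"].values
    lon = field["lon"].values
    lat_ok = (lat >= basin.lat_min) & (lat <= basin.lat_max)

    lo, hi = _lon360(basin.lon_min), _lon360(basin.lon_max)
    lon3 = _lon360(lon)
    if lo == hi and basin.lon_min != basin.lon_max:
        lon_ok = np.ones_like(lon3, bool)  # full 360-degree span
    elif lo <= hi:
        lon_ok = (lon3 >= lo) & (lon3 <= hi)
    else:  # wraps the dateline
        lon_ok = (lon3 >= lo) | (lon3 <= hi)
    if not lat_ok.any() or not lon_ok.any():
        raise ValueError(f"basin {basin.name!r} selects no grid cells")

    out = field.isel(lat=np.where(lat_ok)[0], lon=np.where(lon_ok)[0])
    if lo > hi:
        # roll so the western edge of the box comes first
        sel3 = _lon360(out["lon"].values)
        order = np.argsort(np.mod(sel3 - lo, 360.0))
        out = out.isel(lon=order)
    return out


def regional_mean(
    field: xr.DataArray, box: BasinSpec | None = None, mask: xr.DataArray | None = None
) -> pd.Series:
    """cos(latitude)-weighted spatial mean per month.

    Missing cells are excluded from both numerator and weights; a month with
    no valid cell yields NaN (logged).
    """
    if box is not None:
        field = extract_basin(field, box)
    vals = field.transpose("time", "lat", "lon").values.astype(float)
    w = np.cos(np.deg2rad(field["lat"].values))[:, None]
    w = np.broadcast_to(w, vals.shape[1:])
    if mask is not None:
        m = mask.transpose("lat", "lon").values.astype(bool)
        w = np.where(m, w, 0.0)
    ok = np.isfinite(vals)
    num = np.nansum(np.where(ok, vals, 0.0) * w, axis=(1, 2))
    den = np.sum(ok * w, axis=(1, 2))
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    n_empty = int((den == 0).sum())
    if n_empty:
        logger.warning("regional_mean: %d months with no valid cells -> NaN", n_empty)
    idx = pd.PeriodIndex(field["time"].values, freq="M")
    return pd.Series(out, index=idx, name=field.name)


# ---------------------------------------------------------------------------
# seasonal pooling


@dataclass
class PooledSamples:
    """Paired samples (F(t), O(t), O(t - tau)) pooled over a season's months."""

    f: np.ndarray           # (n,)
    o_t: np.ndarray         # (n, k) forcing at time t
    o_lag: np.ndarray       # (n, k) forcing at time t - tau
    times: pd.PeriodIndex   # the t of each pair
    n_dropped: int
    tau: int
    season: SeasonWindow | None


def pool_season(
    f: pd.Series,
    o: pd.Series | pd.DataFrame,
    season: SeasonWindow | int | None,
    tau: int = 1,
) -> PooledSamples:
    """Pool (F(t), O(t), O(t - tau)) pairs over the months of a 3-month season.

    ``season=None`` pools every month (full-record mode). The lagged forcing
    may come from the month preceding the season; pairs whose lagged month
    precedes the record, or with any missing component, are dropped and
    counted. With an L-year record and no missing data a season yields 3L
    pairs minus boundary losses.
    """
    if isinstance(season, int):
        season = season_window(season)
    if isinstance(o, pd.Series):
        o = o.to_frame()
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau >= len(f):
        raise ValueError("tau must be smaller than the series length")
    if not f.index.equals(o.index):
        raise ValueError("F and O must share one monthly time axis")

    months = f.index.month
    in_season = np.ones(len(f), bool) if season is None else np.isin(months, season.months)
    tpos = np.where(in_season)[0]

    candidates = len(tpos)
    tpos = tpos[tpos - tau >= 0]
    fv = f.values[tpos]
    ov_t = o.values[tpos]
    ov_lag = o.values[tpos - tau]
    ok = np.isfinite(fv) & np.isfinite(ov_t).all(axis=1) & np.isfinite(ov_lag).all(axis=1)
    n_dropped = candidates - int(ok.sum())
    if n_dropped:
        logger.info(
            "pool_season(season=%s): dropped %d of %d pairs (boundary/missing)",
            getattr(season, "index", None), n_dropped, candidates,
        )
    return PooledSamples(
        f=fv[ok],
        o_t=ov_t[ok],
        o_lag=ov_lag[ok],
        times=f.index[tpos[ok]],
        n_dropped=n_dropped,
        tau=tau,
        season=season,
    )
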
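"""Preprocessing: raw monthly inputs -> detrended, volcano-masked annual series.

The analysis works on interannual anomalies: every series and every grid
cell is detrended by removing its long-term ordinary-least-squares linear
trend, and years perturbed by major volcanic eruptions (Agung 1963-64,
El Chichon 1982, Pinatubo 1991-93) are flagged invalid so they never enter
a correlation, regression or coherence computation.

Monthly series are pandas Series with a monthly DatetimeIndex; gridded
fields are xarray DataArrays with dims ("time", "lat", "lon").
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .containers import AnnualSeries, DegenerateInputError

__all__ = [
    "DEFAULT_VOLCANO_YEARS",
    "PPM_TO_PGC",
    "annual_cgr_from_monthly_co2",
    "detrend_linear",
    "exclude_volcano_years",
    "area_weighted_tropical_mean",
    "lagged_annual_precip",
    "annualize_field",
]

#: Years excluded for unusual carbon-flux anomalies after major eruptions.
DEFAULT_VOLCANO_YEARS = frozenset({1963, 1964, 1982, 1991, 1992, 1993})

#: Conversion between a 1 ppm change of global CO2 and airborne carbon mass.
PPM_TO_PGC = 2.124

EARTH_RADIUS_M = 6.371e6


def _monthly_index(co2: pd.Series) -> pd.Series:
    if not isinstance(co2.index, pd.DatetimeIndex):
        raise TypeError("monthly series must have a DatetimeIndex")
    return co2.sort_index()


def annual_cgr_from_monthly_co2(
    co2: pd.Series,
    ppm_to_pgc: float | None = PPM_TO_PGC,
    strategy: Literal["dec_minus_dec", "annual_mean_diff"] = "dec_minus_dec",
) -> AnnualSeries:
    """Annual CO2 growth rate from a monthly concentration series.

    The growth rate of year ``y`` is the concentration increase across that
    calendar year.  With monthly data the operational rule (``strategy=
    "dec_minus_dec"``, the default) is December(y) minus December(y-1) of
    the monthly means; the first year, which has no preceding December, is
    flagged invalid.  ``"annual_mean_diff"`` instead differences calendar-
    year means, a common smoother alternative.

    Parameters
    ----------
    co2 : monthly concentration series (ppm).
    ppm_to_pgc : conversion constant to PgC yr-1, or None to stay in ppm.
    """
    co2 = _monthly_index(co2)
    years = np.unique(co2.index.year)
    values = np.full(years.size, np.nan)
    valid = np.zeros(years.size, dtype=bool)

    by_year = {int(y): co2[co2.index.year == y] for y in years}
    for i, y in enumerate(years):
        if strategy == "dec_minus_dec":
            this_dec = by_year[int(y)][by_year[int(y)].index.month == 12]
            prev = by_year.get(int(y) - 1)
            prev_dec = (
                prev[prev.index.month == 12] if prev is not None else pd.Series(dtype=float)
            )
            if len(this_dec) == 1 and len(prev_dec) == 1:
                values[i] = float(this_dec.iloc[0]) - float(prev_dec.iloc[0])
                valid[i] = True
        elif strategy == "annual_mean_diff":
            prev = by_year.get(int(y) - 1)
            if prev is not None and len(prev) == 12 and len(by_year[int(y)]) == 12:
                values[i] = float(by_year[int(y)].mean()) - float(prev.mean())
                valid[i] = True
        else:
            raise ValueError(f"unknown CGR strategy {strategy!r}")

    units = "ppm yr-1"
    if ppm_to_pgc is not None:
        values = values * ppm_to_pgc
        units = "PgC yr-1"
    return AnnualSeries(years, values, valid, units=units, name="CGR")


def _detrend_matrix(t: np.ndarray, y: np.ndarray, fit_rows: np.ndarray) -> np.ndarray:
    """Remove per-column OLS lines fitted on ``fit_rows`` from all rows of y."""
    x = t[fit_rows].astype(float)
    x0 = x - x.mean()
    denom = float(x0 @ x0)
    if denom == 0.0:
        raise DegenerateInputError("cannot fit a trend to <2 distinct time points")
    yf = y[fit_rows]
    slope = x0 @ (yf - yf.mean(axis=0)) / denom
    intercept = yf.mean(axis=0) - slope * x.mean()
    return y - (np.asarray(t, dtype=float)[:, None] * slope + intercept)


def detrend_linear(obj: AnnualSeries | xr.DataArray) -> AnnualSeries | xr.DataArray:
    """Remove the long-term linear trend, returning interannual anomalies.

    For an :class:`AnnualSeries` the line is fitted over valid years only,
    so excluded outliers cannot tilt the trend; anomalies of invalid years
    are still computed but stay flagged invalid.  For a gridded field each
    cell is detrended independently over the full time axis.
    """
    if isinstance(obj, AnnualSeries):
        if obj.valid.sum() < 3:
            raise DegenerateInputError("need >=3 valid years to detrend")
        anom = _detrend_matrix(obj.years, obj.values[:, None], obj.valid)[:, 0]
        return AnnualSeries(obj.years, anom, obj.valid.copy(),
                            units=obj.units, name=obj.name)
    if isinstance(obj, xr.DataArray):
        if obj.sizes["time"] < 3:
            raise DegenerateInputError("need >=3 time points to detrend")
        nt = obj.sizes["time"]
        flat = obj.transpose("time", "lat", "lon").values.reshape(nt, -1)
        t = np.arange(nt)
        anom = _detrend_matrix(t, flat, np.ones(nt, dtype=bool))
        out = obj.copy()
        out.values = anom.reshape(obj.transpose("time", "lat", "lon").shape)
        return out
    raise TypeError(f"cannot detrend {type(obj).__name__}")


def exclude_volcano_years(
    s: AnnualSeries, volcano_years: set[int] | frozenset[int] = DEFAULT_VOLCANO_YEARS
) -> AnnualSeries:
    """Clear the valid flag of volcanic-eruption years."""
    out = s.copy()
    out.valid &= ~np.isin(out.years, list(volcano_years))
    return out


def _cell_areas_m2(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Areas (m^2) of a regular lat-lon grid, as a (lat, lon) array."""
    dlat = np.deg2rad(abs(float(np.diff(lat).mean())) if lat.size > 1 else 1.0)
    dlon = np.deg2rad(abs(float(np.diff(lon).mean())) if lon.size > 1 else 1.0)
    area = (EARTH_RADIUS_M ** 2) * dlat * dlon * np.cos(np.deg2rad(lat))
    return np.repeat(area[:, None], lon.size, axis=1)


def annualize_field(
    field: xr.DataArray, how: Literal["mean", "sum"] = "mean"
) -> xr.DataArray:
    """Collapse a monthly field to yearly values (mean, or sum for fluxes)."""
    grouped = field.groupby("time.year")
    return grouped.mean("time") if how == "mean" else grouped.sum("time")


def area_weighted_tropical_mean(
    field: xr.DataArray,
    mask: xr.DataArray | None = None,
    band: tuple[float, float] = (-24.0, 24.0),
    mode: Literal["mean", "sum_Tt"] = "mean",
    annual: Literal["mean", "sum"] = "mean",
    weighted: bool = True,
    units: str = "",
    name: str = "",
) -> AnnualSeries:
    """Aggregate a gridded field over vegetated tropical land, per year.

    ``mode="mean"`` gives the cos-latitude-weighted mean over unmasked
    cells within the latitude band (the tropical-temperature convention);
    ``mode="sum_Tt"`` converts a water depth in mm to mass per cell area
    and sums to teratonnes of water, the unit in which water-storage
    sensitivities are expressed.  Monthly inputs are first collapsed to
    yearly values (mean, or ``annual="sum"`` for precipitation).
    """
    if "year" not in field.dims:
        field = annualize_field(field, how=annual)
    lat = field["lat"].values
    lon = field["lon"].values
    in_band = (lat >= band[0]) & (lat <= band[1])

    keep = np.ones((lat.size, lon.size), dtype=bool)
    if mask is not None:
        keep &= mask.values.astype(bool)
    keep &= in_band[:, None]
    if not keep.any():
        raise DegenerateInputError("mask does not intersect the latitude band")

    vals = field.transpose("year", "lat", "lon").values
    if mode == "sum_Tt":
        areas = _cell_areas_m2(lat, lon)
        # 1 mm water over 1 m^2 = 1 kg; 1 Tt = 1e15 kg
        agg = (vals * areas * keep).sum(axis=(1, 2)) / 1.0e15
        out_units, out_name = "Tt H2O", name or "WS"
    else:
        if weighted:
            w = np.cos(np.deg2rad(lat))[:, None] * np.ones(lon.size)
        else:
            w = np.ones((lat.size, lon.size))
        w = w * keep
        agg = (vals * w).sum(axis=(1, 2)) / w.sum()
        out_units, out_name = units or str(field.attrs.get("units", "")), name
    return AnnualSeries(field["year"].values, agg, units=out_units, name=out_name)


def lagged_annual_precip(
    p: pd.Series | xr.DataArray,
    mask: xr.DataArray | None = None,
    band: tuple[float, float] = (-24.0, 24.0),
) -> AnnualSeries:
    """Six-month-lagged yearly precipitation (LagP).

    LagP of year ``y`` is the sum of monthly precipitation from July of
    year ``y-1`` through June of year ``y`` — a proxy for the aggregated
    terrestrial water-storage anomaly, reflecting soil-water memory.
    Years without a complete preceding 12-month window are flagged invalid.
    Gridded input is first reduced to an area-weighted tropical mean.
    """
    if isinstance(p, xr.DataArray):
        lat = p["lat"].values
        lon = p["lon"].values
        keep = np.ones((lat.size, lon.size), dtype=bool)
        if mask is not None:
            keep &= mask.values.astype(bool)
        keep &= ((lat >= band[0]) & (lat <= band[1]))[:, None]
        if not keep.any():
            raise DegenerateInputError("mask does not intersect the latitude band")
        w = np.cos(np.deg2rad(lat))[:, None] * np.ones(lon.size) * keep
        vals = p.transpose("time", "lat", "lon").values
        series = (vals * w).sum(axis=(1, 2)) / w.sum()
        p = pd.Series(series, index=pd.DatetimeIndex(p["time"].values))
    p = _monthly_index(p)

    years = np.unique(p.index.year)
    values = np.full(years.size, np.nan)
    valid = np.zeros(years.size, dtype=bool)
    key = p.index.year * 12 + (p.index.month - 1)
    for i, y in enumerate(years):
        # months Jul(y-1) .. Jun(y)
        window = (key >= (y - 1) * 12 + 6) & (key <= y * 12 + 5)
        if window.sum() == 12:
            values[i] = float(p[window].sum())
            valid[i] = True
    return AnnualSeries(years, values, valid, units="mm yr-1", name="LagP")
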
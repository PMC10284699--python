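"""Nino indices and EP/CP ENSO-type classification from gridded SST.

El Nino events are typed by where their peak sea-surface-temperature
anomaly sits: Eastern-Pacific (EP) events peak east of 150 W, Central-
Pacific (CP) events west of it.  A year is labelled

* EP when the largest DJF SST anomaly in the equatorial scan band
  (2 S - 2 N, 110 E - 90 W) lies east of 150 W and the Nino3 DJF anomaly
  exceeds one standard deviation of its own series;
* CP when the peak lies west of 150 W and Nino4 exceeds one standard
  deviation;
* NEUTRAL otherwise.  A year whose peak side and exceeding index disagree
  is labelled NEUTRAL with a note, since the rule is silent there.

DJF of year y means December(y-1) through February(y); longitudes use the
0-360 degrees-east convention (150 W = 210 E).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .containers import AnnualSeries, EnsoCalendar

__all__ = ["NINO_BOXES", "sst_anomaly", "nino_index", "classify_enso_years"]

#: Standard index regions, (lat_min, lat_max, lon_min, lon_max) deg east.
NINO_BOXES: dict[str, tuple[float, float, float, float]] = {
    "nino3": (-5.0, 5.0, 210.0, 270.0),    # 150 W - 90 W
    "nino4": (-5.0, 5.0, 160.0, 210.0),    # 160 E - 150 W
    "nino34": (-5.0, 5.0, 190.0, 240.0),   # 170 W - 120 W
}

#: Equatorial band scanned for the peak DJF anomaly: 2 S - 2 N, 110 E - 90 W.
SCAN_BAND = (-2.0, 2.0, 110.0, 270.0)

#: EP/CP dividing meridian, 150 W.
EP_CP_BOUNDARY_LON = 210.0


def sst_anomaly(
    sst: xr.DataArray, climatology_window: tuple[int, int] | None = None
) -> xr.DataArray:
    """Remove the per-cell, per-calendar-month climatological mean.

    The climatology is computed over ``climatology_window`` (calendar
    years, inclusive); by default the full record.  Removing a monthly
    climatology also removes any spatially uniform offset, so the
    classification downstream is invariant to adding a constant to all
    SSTs.
    """
    time = pd.DatetimeIndex(sst["time"].values)
    if climatology_window is None:
        climatology_window = (int(time.year.min()), int(time.year.max()))
    y0, y1 = climatology_window
    if y1 < y0:
        raise ValueError("empty climatology window")
    if y1 - y0 + 1 < 10:
        warnings.warn("climatology window shorter than 10 years")
    in_win = (time.year >= y0) & (time.year <= y1)
    if not in_win.any():
        raise ValueError("climatology window outside the record")

    vals = sst.transpose("time", "lat", "lon").values
    months = time.month.values
    anom = vals.copy().astype(float)
    for m in range(1, 13):
        rows = months == m
        clim_rows = rows & in_win
        if clim_rows.any():
            anom[rows] -= vals[clim_rows].mean(axis=0)
    out = sst.copy()
    out.values = anom.reshape(sst.transpose("time", "lat", "lon").shape)
    return out


def _djf_maps(anom: xr.DataArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-year DJF-mean anomaly maps; years lacking any DJF month invalid."""
    time = pd.DatetimeIndex(anom["time"].values)
    vals = anom.transpose("time", "lat", "lon").values
    years = np.unique(time.year)
    maps = np.full((years.size,) + vals.shape[1:], np.nan)
    valid = np.zeros(years.size, dtype=bool)
    for i, y in enumerate(years):
        rows = ((time.year == y - 1) & (time.month == 12)) | (
            (time.year == y) & time.month.isin([1, 2])
        )
        if rows.sum() == 3:
            maps[i] = vals[rows].mean(axis=0)
            valid[i] = True
    return years, maps, valid


def _box_mean(
    maps: np.ndarray, lat: np.ndarray, lon: np.ndarray,
    box: tuple[float, float, float, float],
) -> np.ndarray:
    lat0, lat1, lon0, lon1 = box
    ilat = (lat >= lat0) & (lat <= lat1)
    ilon = (lon >= lon0) & (lon <= lon1)
    if not (ilat.any() and ilon.any()):
        raise ValueError(f"box {box} outside the grid")
    w = np.cos(np.deg2rad(lat[ilat]))[:, None] * np.ones(ilon.sum())
    sub = maps[:, ilat][:, :, ilon]
    return (sub * w).sum(axis=(1, 2)) / w.sum()


def nino_index(
    anom: xr.DataArray, box: str | tuple[float, float, float, float]
) -> AnnualSeries:
    """DJF-mean, area-weighted SST anomaly over a Nino box, per year.

    ``box`` is one of the named regions in :data:`NINO_BOXES` or an
    explicit (lat_min, lat_max, lon_min, lon_max) tuple.  The value of
    year y averages December(y-1) through February(y); the first year,
    which lacks a preceding December, is flagged invalid.
    """
    name = box if isinstance(box, str) else "nino_custom"
    if isinstance(box, str):
        box = NINO_BOXES[box]
    years, maps, valid = _djf_maps(anom)
    vals = np.full(years.size, np.nan)
    if valid.any():
        vals[valid] = _box_mean(
            maps[valid], anom["lat"].values, anom["lon"].values, box
        )
    return AnnualSeries(years, vals, valid, units="K", name=name)


def classify_enso_years(
    anom: xr.DataArray,
    climatology_window: tuple[int, int] | None = None,
    detrend: bool = False,
) -> EnsoCalendar:
    """Label each year EP, CP or NEUTRAL from a gridded SST anomaly field.

    Standard-deviation thresholds are those of the DJF index series over
    ``climatology_window`` (default: all valid years); exceedance is
    strict.  ``detrend`` removes a per-cell linear trend before
    classification (off by default: anomalies relative to climatology are
    classified as-is).
    """
    if detrend:
        from .preprocess import detrend_linear

        anom = detrend_linear(anom)

    n3 = nino_index(anom, "nino3")
    n4 = nino_index(anom, "nino4")
    n34 = nino_index(anom, "nino34")
    years, maps, valid = _djf_maps(anom)
    lat = anom["lat"].values
    lon = anom["lon"].values

    lat0, lat1, lon0, lon1 = SCAN_BAND
    ilat = (lat >= lat0) & (lat <= lat1)
    ilon = (lon >= lon0) & (lon <= lon1)
    band_lon = lon[ilon]

    peak_lon = np.full(years.size, np.nan)
    for i in np.flatnonzero(valid):
        band = maps[i][ilat][:, ilon]
        j = int(np.argmax(band.max(axis=0)))
        peak_lon[i] = band_lon[j]

    def _threshold(s: AnnualSeries) -> float:
        sel = s.valid.copy()
        if climatology_window is not None:
            sel &= (s.years >= climatology_window[0]) & (s.years <= climatology_window[1])
        vals = s.values[sel]
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    sd3, sd4 = _threshold(n3), _threshold(n4)

    labels = np.full(years.size, "NEUTRAL", dtype=object)
    notes: dict[int, str] = {}
    for i in np.flatnonzero(valid):
        east = peak_lon[i] > EP_CP_BOUNDARY_LON
        n3_hit = n3.values[i] > sd3
        n4_hit = n4.values[i] > sd4
        if east and n3_hit:
            labels[i] = "EP"
        elif (not east) and n4_hit:
            labels[i] = "CP"
        elif (east and n4_hit) or ((not east) and n3_hit):
            notes[int(years[i])] = (
                "peak side and exceeding index disagree; labelled NEUTRAL"
            )
    return EnsoCalendar(
        years=years,
        labels=labels.astype(str),
        nino3=n3.values,
        nino4=n4.values,
        nino34=n34.values,
        peak_longitude=peak_lon,
        valid=valid,
        notes=notes,
    )
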
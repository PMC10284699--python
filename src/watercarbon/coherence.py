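"""Spatial coherence of tropical water-storage anomalies.

Local water anomalies control local carbon fluxes, but their aggregated
effect on the global CO2 growth rate depends on whether the anomalies are
spatially coherent (one sign across the tropics, typical of ENSO years) or
spatially compensating (wet regions offsetting dry ones).  The coherence
statistic captures this through the cell-pair covariance structure: with
c_ij the temporal covariance of the anomaly series of cells i and j,

    coherence = 100 * (tcov+ + tcov-) / tcov,
    tcov  = sum_{i != j} |c_ij|,   tcov+/- the positive/negative parts,

diagonal terms excluded (variances are always positive and carry no
coherence information).  100% means every cell pair co-varies with one
sign; negative values mean compensation dominates.

A per-year variant restricts the same formula to a single year's
outer-product contribution: with x_i the anomaly of cell i in year t,

    coherence(t) = 100 * [(sum x_i)^2 - sum x_i^2]
                       / [(sum |x_i|)^2 - sum x_i^2],

which is the pairwise sum sum_{i != j} x_i x_j over sum_{i != j} |x_i x_j|
in closed form.  Years are binned into coherence terciles (LOW / MEDIUM /
HIGH) and the water-CGR coupling is re-estimated within each bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .containers import (
    AnnualSeries,
    CoherenceSeries,
    DegenerateInputError,
    align_series,
)
from .coupling import _corr_pvalue, _partial_arr, _pearson_arr

__all__ = [
    "period_coherence",
    "yearly_coherence",
    "coherence_fraction",
    "subset_coupling",
]


def _flatten_field(
    anom: xr.DataArray, mask: xr.DataArray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (years, data[year, cell], cell_lats) for unmasked cells."""
    if "year" in anom.dims:
        anom = anom.transpose("year", "lat", "lon")
        years = anom["year"].values
    elif "time" in anom.dims:
        anom = anom.transpose("time", "lat", "lon")
        years = np.asarray(anom["time"].values)
        if not np.issubdtype(years.dtype, np.integer):
            raise ValueError("expected yearly anomalies (integer time axis)")
    else:
        raise ValueError("anomaly field must have a 'year' or 'time' dim")
    lat = anom["lat"].values
    nlat, nlon = lat.size, anom["lon"].values.size
    data = anom.values.reshape(years.size, nlat * nlon)
    lats = np.repeat(lat, nlon)
    if mask is not None:
        keep = mask.values.astype(bool).ravel()
        data = data[:, keep]
        lats = lats[keep]
    return np.asarray(years, dtype=int), data, lats


def period_coherence(
    anom: xr.DataArray,
    window: tuple[int, int] | None = None,
    mask: xr.DataArray | None = None,
    area_weighted: bool = False,
    block_size: int = 512,
) -> float:
    """Spatial coherence (percent) of a yearly anomaly field over a period.

    The all-pairs covariance sums are accumulated blockwise so the full
    cell-by-cell covariance matrix is never materialized.  Optional area
    weighting multiplies each pair term by cos(lat_i) cos(lat_j).
    """
    years, data, lats = _flatten_field(anom, mask)
    if window is not None:
        sel = (years >= window[0]) & (years <= window[1])
        data = data[sel]
    n_years, n_cells = data.shape
    if n_years < 3:
        raise DegenerateInputError("need >=3 years in the window")
    if n_cells < 2:
        raise DegenerateInputError("need >=2 unmasked cells")

    A = data - data.mean(axis=0)
    if area_weighted:
        A = A * np.sqrt(np.cos(np.deg2rad(lats)))
    A = A / np.sqrt(n_years - 1)  # so A.T @ A is the covariance matrix

    signed = 0.0
    total = 0.0
    diag = np.einsum("ti,ti->i", A, A)
    for start in range(0, n_cells, block_size):
        block = A[:, start:start + block_size]
        C = block.T @ A  # (block, n_cells) covariance rows
        signed += C.sum()
        total += np.abs(C).sum()
    signed -= diag.sum()
    total -= diag.sum()
    if total <= 0.0:
        raise DegenerateInputError("all pairwise covariances vanish")
    return float(100.0 * signed / total)


def _tercile_bins(coh: np.ndarray, valid: np.ndarray) -> np.ndarray:
    bins = np.full(coh.shape, "", dtype=object)
    vals = coh[valid]
    if vals.size == 0:
        return bins.astype(str)
    q1, q2 = np.percentile(vals, [100.0 / 3.0, 200.0 / 3.0])
    for i in np.flatnonzero(valid):
        if coh[i] <= q1:
            bins[i] = "LOW"
        elif coh[i] <= q2:
            bins[i] = "MEDIUM"
        else:
            bins[i] = "HIGH"
    return bins.astype(str)


def yearly_coherence(
    anom: xr.DataArray,
    mask: xr.DataArray | None = None,
    area_weighted: bool = False,
) -> CoherenceSeries:
    """Per-year spatial coherence with tercile bins.

    Each year's value applies the pairwise formula to that year's anomaly
    map alone (its contribution to the covariance sums), via the O(cells)
    closed form.  Years with fewer than two nonzero-anomaly cells, or with
    a vanishing pairwise denominator, are flagged invalid.  Tercile bins
    are assigned jointly over all valid years.
    """
    years, data, lats = _flatten_field(anom, mask)
    if area_weighted:
        data = data * np.cos(np.deg2rad(lats))
    coh = np.full(years.size, np.nan)
    valid = np.zeros(years.size, dtype=bool)
    for t in range(years.size):
        u = data[t]
        if np.count_nonzero(u) < 2:
            continue
        s1 = u.sum()
        s2 = (u ** 2).sum()
        sa = np.abs(u).sum()
        denom = sa ** 2 - s2
        if denom <= 0.0:
            continue
        coh[t] = 100.0 * (s1 ** 2 - s2) / denom
        valid[t] = True
    return CoherenceSeries(years, coh, _tercile_bins(coh, valid), valid)


def coherence_fraction(cs: CoherenceSeries, window: tuple[int, int]) -> float:
    """Fraction of valid in-window years in the HIGH coherence tercile.

    Bins are expected to have been assigned over the full record so that
    fractions from different windows are comparable.
    """
    sel = (cs.years >= window[0]) & (cs.years <= window[1]) & cs.valid
    if not sel.any():
        raise ValueError(f"no valid years in window {window}")
    return float(np.mean(cs.bins[sel] == "HIGH"))


def subset_coupling(
    cs: CoherenceSeries,
    cgr: AnnualSeries,
    ws: AnnualSeries,
    temp: AnnualSeries,
    min_size: int = 5,
) -> pd.DataFrame:
    """Water-CGR coupling conditioned on the coherence tercile.

    Within each bin the Pearson correlation of WS vs CGR and the partial
    correlation controlling temperature are computed over the bin's valid
    years, with t-approximation p-values.  Bins below ``min_size`` years
    are reported with NaN statistics rather than raising.
    """
    rows = []
    for b in ("LOW", "MEDIUM", "HIGH"):
        bin_years = cs.years[(cs.bins == b) & cs.valid]
        sub_cgr, sub_ws, sub_t = (
            _restrict(s, bin_years) for s in (cgr, ws, temp)
        )
        yrs, (c, w, t) = align_series(sub_cgr, sub_ws, sub_t)
        row: dict[str, object] = {"bin": b, "n_years": int(yrs.size)}
        if yrs.size < min_size:
            row.update(r_ws_cgr=np.nan, p_r=np.nan, r_ws_cgr_t=np.nan, p_partial=np.nan)
        else:
            r = _pearson_arr(w, c)
            rp = _partial_arr(w, c, t)
            if np.isnan(r) or np.isnan(rp):
                row.update(r_ws_cgr=np.nan, p_r=np.nan, r_ws_cgr_t=np.nan, p_partial=np.nan)
            else:
                row.update(
                    r_ws_cgr=r,
                    p_r=_corr_pvalue(r, yrs.size),
                    r_ws_cgr_t=rp,
                    p_partial=_corr_pvalue(rp, yrs.size, n_controls=1),
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["significant_05"] = df["p_r"] < 0.05
    return df


def _restrict(s: AnnualSeries, years: np.ndarray) -> AnnualSeries:
    out = s.copy()
    out.valid &= np.isin(out.years, years)
    return out
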
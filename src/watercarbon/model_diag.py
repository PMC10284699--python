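"""Model-ensemble diagnosis: coupling metrics and EOF decomposition.

Applies the observational water-carbon coupling metrics to prepared
model series (tropical soil moisture, global NEE, tropical temperature)
across fixed windows, and decomposes gridded soil-moisture anomalies
into empirical orthogonal functions.  The diagnosis question is whether
a model's water-carbon coupling strengthens between an early and a
recent window, as observed, or stays persistently high.

NEE is ecosystem respiration minus photosynthesis, so a carbon sink is
negative; correlations are stored as computed and their sign is left to
interpretation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .containers import AnnualSeries, DegenerateInputError, EofResult, ModelBundle
from .coupling import ols_sensitivity, partial_corr, pearson_corr
from .preprocess import detrend_linear

__all__ = [
    "ensemble_coupling_table",
    "eof_decompose",
    "observational_combinations",
]

#: Default diagnosis windows (27 years each; the year between them is shared
#: with neither).
DEFAULT_WINDOWS = ((1960, 1986), (1988, 2014))


def _window_detrended(s: AnnualSeries, window: tuple[int, int]) -> AnnualSeries:
    return detrend_linear(s.subset(*window))


def ensemble_coupling_table(
    bundles: Sequence[ModelBundle],
    windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    boot_reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy model x window x statistic table with ensemble summary rows.

    For each model and window (re-detrended within the window) the table
    holds the water-NEE correlation, the partial correlation controlling
    temperature, and the OLS sensitivity of NEE to water.  Summary rows
    give the ensemble median, interquartile range and 5th-95th
    percentiles per window and statistic, matching box-plot statistics.
    Windows with fewer than 10 valid years are skipped with a warning.
    """
    if not bundles:
        raise ValueError("need at least one model bundle")
    rows = []
    for b in bundles:
        for w in windows:
            try:
                sm = _window_detrended(b.soil_moisture, w)
                ne = _window_detrended(b.nee, w)
                tp = _window_detrended(b.temperature, w)
            except ValueError:
                warnings.warn(f"{b.model_name}: window {w} outside span; skipped")
                continue
            n_valid = int((sm.valid & ne.valid & tp.valid).sum())
            if n_valid < 10:
                warnings.warn(
                    f"{b.model_name}: window {w} has {n_valid} valid years; skipped"
                )
                continue
            r, p_r = pearson_corr(sm, ne)
            rp, p_rp = partial_corr(sm, ne, tp)
            sens = ols_sensitivity(ne, sm, n_reps=max(boot_reps, 10), seed=seed)
            for stat, val, p in (
                ("R_water_nee", r, p_r),
                ("R_water_nee|temp", rp, p_rp),
                ("gamma_water", sens.gamma, np.nan),
            ):
                rows.append(
                    {
                        "model": b.model_name,
                        "window_start": w[0],
                        "window_end": w[1],
                        "statistic": stat,
                        "value": val,
                        "p_value": p,
                        "n_years": n_valid,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    summaries = []
    for (w0, w1, stat), grp in df.groupby(
        ["window_start", "window_end", "statistic"]
    ):
        v = grp["value"].to_numpy()
        q05, q25, q50, q75, q95 = np.percentile(v, [5, 25, 50, 75, 95])
        summaries.append(
            {
                "window_start": w0, "window_end": w1, "statistic": stat,
                "median": q50, "iqr_lo": q25, "iqr_hi": q75,
                "p5": q05, "p95": q95, "n_models": len(grp),
            }
        )
    df.attrs["summary"] = pd.DataFrame(summaries)
    return df


def observational_combinations(
    water: dict[str, AnnualSeries],
    carbon: dict[str, AnnualSeries],
    temperature: AnnualSeries,
) -> list[ModelBundle]:
    """Enumerate observational variable pairings as pseudo-bundles.

    The observational rows of the diagnosis table cross each carbon-flux
    series (CGR, and the residual land sink when available) with each
    water proxy (WS, LagP), each paired with the same temperature series
    — four combinations in the standard setup.
    """
    out = []
    for cname, cs in carbon.items():
        for wname, wsr in water.items():
            out.append(
                ModelBundle(
                    model_name=f"obs:{cname}~{wname}",
                    soil_moisture=wsr,
                    nee=cs,
                    temperature=temperature,
                )
            )
    return out


def eof_decompose(grid: xr.DataArray, n_modes: int) -> EofResult:
    """EOF modes of a yearly anomaly field via singular decomposition.

    The (time x cells) anomaly matrix is weighted by sqrt(cos latitude)
    before the SVD so that variance contributions are area-faithful;
    patterns are returned in physical units (weighting undone) and the
    per-mode principal-component series reproduce the field when all
    modes are retained.  Sign convention: the largest-magnitude loading
    of each pattern is positive.
    """
    if "year" in grid.dims:
        tdim = "year"
    elif "time" in grid.dims:
        tdim = "time"
    else:
        raise ValueError("field must have a 'year' or 'time' dim")
    grid = grid.transpose(tdim, "lat", "lon")
    years = np.asarray(grid[tdim].values)
    lat = grid["lat"].values
    nt = years.size
    if nt < n_modes:
        raise DegenerateInputError("fewer time steps than requested modes")

    w = np.sqrt(np.cos(np.deg2rad(lat)))
    X = (grid.values * w[None, :, None]).reshape(nt, -1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_modes > rank:
        warnings.warn(f"requested {n_modes} modes but rank is {rank}; truncating")
        n_modes = rank

    total = float((s ** 2).sum())
    expl = (s[:n_modes] ** 2) / total if total > 0 else np.zeros(n_modes)

    patterns, pcs = [], []
    shape = grid.values.shape[1:]
    for k in range(n_modes):
        pat = (Vt[k].reshape(shape)) / w[:, None]
        pc = U[:, k] * s[k]
        imax = np.unravel_index(np.argmax(np.abs(pat)), pat.shape)
        if pat[imax] < 0:
            pat, pc = -pat, -pc
        patterns.append(
            xr.DataArray(
                pat, coords={"lat": lat, "lon": grid["lon"].values},
                dims=("lat", "lon"), name=f"eof_{k + 1}",
            )
        )
        if np.issubdtype(years.dtype, np.integer):
            pcs.append(AnnualSeries(years, pc, name=f"pc_{k + 1}"))
        else:
            pcs.append(AnnualSeries(np.arange(nt), pc, name=f"pc_{k + 1}"))
    return EofResult(patterns=patterns, pcs=pcs, explained_variance=expl)
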
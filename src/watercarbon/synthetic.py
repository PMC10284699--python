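"""Synthetic study data with the statistical structure the analysis assumes.

The generator produces every input the pipeline consumes — monthly CO2,
gridded terrestrial water storage, precipitation and temperature over a
tropical land domain, equatorial-Pacific SST, a vegetation mask and a
land-cover map — from a single seeded configuration, together with a
``truth`` record sufficient to recompute every derived series exactly.

Generative model, per year y:

* An ENSO schedule assigns each year EP, CP or NEUTRAL.  Event years get
  a strength e_y (amplitude_sd units, mildly varying); neutral years 0.
* Water storage: in event years the anomaly field loads on a one-signed
  coherent spatial pattern with aggregated amplitude w_y = -e_y Tt
  (droughts during El Nino); in neutral years it loads on a spatially
  compensating dipole pattern whose area-weighted aggregate vanishes,
  plus independent cell noise.  The aggregate tropical WS anomaly is
  therefore large in event years and near zero otherwise.
* Temperature: T_y = temp_enso_coef * e_y + noise (warm El Nino years),
  so water and temperature anomalies are collinear through ENSO.
* CO2 growth rate: CGR_y = gamma_ws * W_y + gamma_t * T_y + noise, on a
  linear trend, where W_y and T_y are the actual area-aggregated
  anomalies; monthly CO2 is the running integral of CGR (in ppm, using a
  configurable airborne conversion) so the December-minus-December rule
  inverts the generator exactly.  A seasonal cycle of configurable
  amplitude (default 0) cancels in December-to-December differences.
* SST: a deterministic monthly climatology plus DJF anomaly blobs placed
  east of 150 W (EP years, exceeding Nino3 variability) or west of it
  (CP years, exceeding Nino4 variability); optional cell noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .containers import AnnualSeries, ModelBundle
from .preprocess import area_weighted_tropical_mean, annualize_field

__all__ = [
    "SyntheticConfig",
    "StudyDataset",
    "generate_study_dataset",
    "generate_sst_with_enso",
    "generate_vod_agc_pair",
    "generate_model_ensemble",
    "regime_schedule",
]

LABELS = ("EP", "CP", "NEUTRAL")


def regime_schedule(
    years: Sequence[int],
    break_year: int,
    era1_probs: tuple[float, float] = (0.0, 0.0),
    era2_probs: tuple[float, float] = (0.10, 0.40),
    seed: int = 0,
) -> np.ndarray:
    """Two-era ENSO schedule: NEUTRAL-dominated era 1, CP-enriched era 2.

    ``era*_probs`` are the (EP, CP) fractions; counts are rounded so the
    composition of each era is deterministic, with the ordering shuffled
    by ``seed``.
    """
    years = np.asarray(years, dtype=int)
    rng = np.random.default_rng(seed)
    out = np.empty(years.size, dtype=object)
    for era_sel, (p_ep, p_cp) in (
        (years < break_year, era1_probs),
        (years >= break_year, era2_probs),
    ):
        n = int(era_sel.sum())
        n_ep, n_cp = int(round(p_ep * n)), int(round(p_cp * n))
        labels = (["EP"] * n_ep + ["CP"] * n_cp + ["NEUTRAL"] * (n - n_ep - n_cp))
        rng.shuffle(labels)
        out[era_sel] = labels
    return out.astype(str)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study dataset.

    Units: ``gamma_ws`` PgC yr-1 per Tt H2O, ``gamma_t`` PgC yr-1 per K,
    ``noise_sd_cgr`` PgC yr-1, ``trend_slopes`` per year in the units of
    each variable.  ``enso_amplitude_sd`` scales event strength in the
    standard-deviation units the classifier uses.
    """

    years_start: int = 1959
    years_end: int = 2018
    grid_shape: tuple[int, int] = (12, 24)
    gamma_ws: float = -1.0
    gamma_t: float = 2.0
    noise_sd_cgr: float = 0.5
    enso_schedule: np.ndarray | None = None
    coherent_pattern: np.ndarray | None = None
    dipole_pattern: np.ndarray | None = None
    trend_slopes: dict[str, float] = dc_field(
        default_factory=lambda: {"cgr": 0.02, "ws": 0.0, "temp": 0.015, "precip": 0.0}
    )
    seed: int = 0
    # secondary knobs
    enso_amplitude_sd: float = 2.0
    temp_enso_coef: float = 0.15      # K per unit event strength
    temp_noise_sd: float = 0.15       # K, ENSO-independent temperature IAV
    ws_cell_noise_sd: float = 0.25    # relative to the coherent pattern RMS
    dipole_amplitude: float = 1.0     # neutral-year dipole loading s.d.
    seasonal_amplitude: float = 0.0   # ppm, CO2 seasonal cycle
    ppm_to_pgc: float = 2.124
    co2_base: float = 315.0           # ppm at the start of the record
    sst_noise_sd: float = 0.0         # K, per-cell monthly SST noise
    lagp_clim: float = 100.0          # mm per month, precipitation base

    def __post_init__(self) -> None:
        if self.years_end <= self.years_start:
            raise ValueError("years_end must exceed years_start")
        if min(self.grid_shape) < 2:
            raise ValueError("grid_shape components must be >= 2")
        if self.enso_schedule is not None:
            self.enso_schedule = np.asarray(self.enso_schedule, dtype=str)
            if self.enso_schedule.size != self.n_years:
                raise ValueError("schedule length must equal the year count")
            bad = set(self.enso_schedule) - set(LABELS)
            if bad:
                raise ValueError(f"unknown schedule labels: {sorted(bad)}")
        for name, pat in (("coherent", self.coherent_pattern),
                          ("dipole", self.dipole_pattern)):
            if pat is not None and np.shape(pat) != tuple(self.grid_shape):
                raise ValueError(f"{name}_pattern shape must match grid_shape")
        if self.coherent_pattern is not None:
            signs = np.sign(self.coherent_pattern[self.coherent_pattern != 0])
            if signs.size and not (np.all(signs > 0) or np.all(signs < 0)):
                raise ValueError("coherent_pattern entries must share one sign")

    @property
    def n_years(self) -> int:
        return self.years_end - self.years_start + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.years_start, self.years_end + 1)


@dataclass
class StudyDataset:
    """All pipeline inputs for one synthetic study, plus the ground truth."""

    co2_monthly: pd.Series
    ws: xr.DataArray
    precip: xr.DataArray
    temp: xr.DataArray
    sst: xr.DataArray
    veg_mask: xr.DataArray
    landcover: xr.DataArray
    truth: dict


# ---------------------------------------------------------------------------
# grids and patterns

def _tropical_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    nlat, nlon = shape
    lat = np.linspace(-22.0, 22.0, nlat)
    lon = np.linspace(0.0, 360.0, nlon, endpoint=False)
    return lat, lon


def _default_patterns(
    lat: np.ndarray, lon: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-signed coherent loading and an area-compensating zonal dipole."""
    L = np.cos(np.deg2rad(lat))[:, None]
    phase = 2.0 * np.pi * np.arange(lon.size) / lon.size
    coherent = (1.0 + 0.8 * np.cos(phase)[None, :] * np.cos(np.pi * lat / 90.0)[:, None])
    # sin over a full uniform period sums to zero row-wise, so the
    # cos-lat / area-weighted aggregate vanishes exactly
    dipole = L * np.sin(phase)[None, :]
    return coherent, dipole


def _monthly_time(y0: int, y1: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")


def _field(
    monthly: np.ndarray, time: pd.DatetimeIndex, lat: np.ndarray,
    lon: np.ndarray, units: str, name: str,
) -> xr.DataArray:
    return xr.DataArray(
        monthly,
        coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"),
        name=name,
        attrs={"units": units},
    )


def _event_strength(
    schedule: np.ndarray, amplitude_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-year ENSO strength: 0 in neutral years, mildly varying otherwise."""
    e = np.zeros(schedule.size)
    events = schedule != "NEUTRAL"
    e[events] = amplitude_sd * (1.0 + 0.2 * np.abs(rng.standard_normal(events.sum())))
    return e


# ---------------------------------------------------------------------------
# SST generator

def generate_sst_with_enso(
    years: Sequence[int],
    schedule: Sequence[str],
    amplitude_sd: float = 2.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    include_lead_year: bool = True,
) -> xr.DataArray:
    """Monthly equatorial-Pacific SST realizing a scripted ENSO calendar.

    EP years place a DJF anomaly blob at 120 W (east of the 150 W
    boundary, inside the Nino3 box); CP years at 175 E (west of it,
    inside Nino4); the blob's box-averaged index exceeds one standard
    deviation of the resulting index series for amplitudes of order one
    and realistic event fractions.  Neutral years carry only the
    climatology (plus optional cell noise).  With ``include_lead_year``
    the field starts one calendar year early so the first scheduled
    year has a complete December-February season.
    """
    years = np.asarray(years, dtype=int)
    schedule = np.asarray(schedule, dtype=str)
    if schedule.size != years.size:
        raise ValueError("schedule must cover all years")
    bad = set(schedule) - set(LABELS)
    if bad:
        raise ValueError(f"unknown schedule labels: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    lat = np.arange(-10.0, 10.1, 2.0)
    lon = np.arange(110.0, 280.1, 2.0)
    y0 = int(years.min()) - (1 if include_lead_year else 0)
    time = _monthly_time(y0, int(years.max()))

    # deterministic climatology: warm pool + seasonal cycle
    clim = 300.0 - 0.01 * lat[:, None] ** 2 - 0.005 * (lon[None, :] - 150.0)
    month_cycle = 0.5 * np.cos(2.0 * np.pi * (time.month.values - 3) / 12.0)
    vals = clim[None, :, :] + month_cycle[:, None, None]
    if noise_sd > 0:
        vals = vals + noise_sd * rng.standard_normal(
            (time.size, lat.size, lon.size)
        )

    centers = {"EP": 240.0, "CP": 185.0}  # 120 W and 175 E
    sig_lon, sig_lat = 15.0, 4.0
    strength = _event_strength(schedule, amplitude_sd, rng)
    tyear, tmonth = time.year.values, time.month.values
    for y, lab, e in zip(years, schedule, strength):
        if lab == "NEUTRAL":
            continue
        blob = 0.4 * e * np.exp(
            -((lat[:, None] / sig_lat) ** 2 + ((lon[None, :] - centers[lab]) / sig_lon) ** 2)
            / 2.0
        )
        rows = ((tyear == y - 1) & (tmonth == 12)) | (
            (tyear == y) & np.isin(tmonth, [1, 2])
        )
        vals[rows] += blob[None, :, :]
    return _field(vals, time, lat, lon, "K", "sst")


# ---------------------------------------------------------------------------
# full study dataset

def generate_study_dataset(config: SyntheticConfig) -> StudyDataset:
    """Generate every pipeline input from one seeded configuration.

    See the module docstring for the generative model.  The ``truth``
    record holds the exact aggregated anomaly series and the CGR draw, so
    recovery tests can compare pipeline output against the construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years
    lat, lon = _tropical_grid(cfg.grid_shape)
    time = _monthly_time(cfg.years_start, cfg.years_end)

    schedule = cfg.enso_schedule
    if schedule is None:
        schedule = rng.choice(LABELS, size=cfg.n_years, p=[0.15, 0.15, 0.70])
    schedule = np.asarray(schedule, dtype=str)

    coherent, dipole = _default_patterns(lat, lon)
    if cfg.coherent_pattern is not None:
        coherent = np.asarray(cfg.coherent_pattern, dtype=float)
    if cfg.dipole_pattern is not None:
        dipole = np.asarray(cfg.dipole_pattern, dtype=float)

    veg_mask = xr.DataArray(
        np.ones((lat.size, lon.size), dtype=bool),
        coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), name="veg_mask",
    )
    classes = np.array(["forest", "shrubland", "savannah", "grassland"])
    landcover = xr.DataArray(
        rng.choice(classes, size=(lat.size, lon.size), p=[0.4, 0.2, 0.2, 0.2]),
        coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), name="landcover",
    )

    # normalize the coherent pattern so unit loading aggregates to 1 Tt H2O
    unit = _field(coherent[None, :, :], _monthly_time(cfg.years_start, cfg.years_start)[:1],
                  lat, lon, "mm", "unit")
    unit_agg = area_weighted_tropical_mean(
        annualize_field(unit), mask=veg_mask, mode="sum_Tt"
    ).values[0]
    coherent = coherent / unit_agg
    rms_c = float(np.sqrt(np.mean(coherent ** 2)))
    dip_rms = float(np.sqrt(np.mean(dipole ** 2)))
    if dip_rms > 0:
        dipole = dipole * (rms_c / dip_rms)

    strength = _event_strength(schedule, cfg.enso_amplitude_sd, rng)
    events = schedule != "NEUTRAL"

    # annual WS anomaly maps (mm water equivalent)
    ws_annual = np.zeros((cfg.n_years, lat.size, lon.size))
    dipole_load = cfg.dipole_amplitude * rng.standard_normal(cfg.n_years)
    for i in range(cfg.n_years):
        if events[i]:
            ws_annual[i] = -strength[i] * coherent  # El Nino droughts
        else:
            ws_annual[i] = dipole_load[i] * dipole
    if cfg.ws_cell_noise_sd > 0:
        ws_annual += (cfg.ws_cell_noise_sd * rms_c) * rng.standard_normal(ws_annual.shape)

    # annual temperature anomaly maps (K)
    t_anom = cfg.temp_enso_coef * strength + cfg.temp_noise_sd * rng.standard_normal(
        cfg.n_years
    )
    temp_annual = t_anom[:, None, None] + 0.05 * rng.standard_normal(
        (cfg.n_years, lat.size, lon.size)
    )

    # exact aggregated truths, computed with the pipeline's own aggregator
    def _annual_to_da(arr: np.ndarray, units: str, name: str) -> xr.DataArray:
        return xr.DataArray(
            arr, coords={"year": years, "lat": lat, "lon": lon},
            dims=("year", "lat", "lon"), name=name, attrs={"units": units},
        )

    w_agg = area_weighted_tropical_mean(
        _annual_to_da(ws_annual, "mm", "ws"), mask=veg_mask, mode="sum_Tt"
    )
    t_agg = area_weighted_tropical_mean(
        _annual_to_da(temp_annual, "K", "temp"), mask=veg_mask, mode="mean",
        units="K", name="T",
    )

    cgr_noise = cfg.noise_sd_cgr * rng.standard_normal(cfg.n_years)
    cgr = (
        cfg.gamma_ws * w_agg.values
        + cfg.gamma_t * t_agg.values
        + cgr_noise
        + cfg.trend_slopes.get("cgr", 0.0) * np.arange(cfg.n_years)
        + 2.0  # baseline growth, PgC yr-1
    )

    # monthly CO2: running integral of CGR so Dec-minus-Dec inverts exactly
    cgr_ppm = cgr / cfg.ppm_to_pgc
    dec_levels = cfg.co2_base + np.cumsum(cgr_ppm)
    co2_vals = np.empty(time.size)
    month_frac = (time.month.values) / 12.0
    year_idx = time.year.values - cfg.years_start
    prev_dec = np.concatenate([[cfg.co2_base], dec_levels[:-1]])
    co2_vals = prev_dec[year_idx] + cgr_ppm[year_idx] * month_frac
    if cfg.seasonal_amplitude:
        co2_vals += cfg.seasonal_amplitude * np.sin(
            2.0 * np.pi * (time.month.values - 4) / 12.0
        )
    co2 = pd.Series(co2_vals, index=time, name="co2")

    # expand annual anomaly maps to monthly fields with linear trends
    tfrac = (np.arange(time.size) / 12.0)
    yix = year_idx
    ws_monthly = ws_annual[yix] + cfg.trend_slopes.get("ws", 0.0) * tfrac[:, None, None]
    temp_monthly = (
        temp_annual[yix] + cfg.trend_slopes.get("temp", 0.0) * tfrac[:, None, None]
    )

    # precipitation: the 12-month window Jul(y-1)..Jun(y) loads on the
    # coherent pattern with the event-year aggregate, so LagP tracks WS
    lag_year = np.where(time.month.values <= 6, time.year.values, time.year.values + 1)
    w_of_year = dict(zip(years.tolist(), w_agg.values))
    precip_monthly = np.full((time.size, lat.size, lon.size), cfg.lagp_clim)
    pattern_mm = coherent / float(
        np.mean(coherent * np.cos(np.deg2rad(lat))[:, None])
        / float(np.mean(np.cos(np.deg2rad(lat))))
    )
    for m in range(time.size):
        wy = w_of_year.get(int(lag_year[m]), 0.0)
        precip_monthly[m] += (wy / 12.0) * pattern_mm
    precip_monthly += cfg.trend_slopes.get("precip", 0.0) * tfrac[:, None, None]

    sst = generate_sst_with_enso(
        years, schedule, amplitude_sd=cfg.enso_amplitude_sd,
        seed=cfg.seed + 1, noise_sd=cfg.sst_noise_sd, include_lead_year=False,
    )
    # align the SST time axis with the land fields
    sst = sst.sel(time=slice(time[0], time[-1]))

    truth = {
        "config": cfg,
        "schedule": schedule,
        "event_strength": strength,
        "w_agg_Tt": w_agg.values.copy(),
        "t_agg_K": t_agg.values.copy(),
        "cgr_pgc": cgr.copy(),
        "cgr_noise": cgr_noise,
        "years": years,
    }
    return StudyDataset(
        co2_monthly=co2,
        ws=_field(ws_monthly, time, lat, lon, "mm", "ws"),
        precip=_field(precip_monthly, time, lat, lon, "mm month-1", "precip"),
        temp=_field(temp_monthly, time, lat, lon, "K", "temp"),
        sst=sst,
        veg_mask=veg_mask,
        landcover=landcover,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# VOD / AGC and model-ensemble generators

def generate_vod_agc_pair(
    params: tuple[float, float, float, float],
    n_cells: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
    vod_range: tuple[float, float] = (0.05, 1.2),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired VOD and aboveground-carbon cell values from the arctan law.

    AGC follows the saturating four-parameter mapping plus Gaussian noise
    (MgC ha-1); VOD is sampled uniformly over ``vod_range``.
    """
    from .vod_agc import arctan_agc

    a, b, c, d = params
    if b <= 0:
        raise ValueError("parameter b must be positive")
    if n_cells < 10:
        raise ValueError("need at least 10 cells")
    rng = np.random.default_rng(seed)
    vod = rng.uniform(*vod_range, size=n_cells)
    agc = arctan_agc(vod, a, b, c, d) + noise_sd * rng.standard_normal(n_cells)
    return vod, agc


def generate_model_ensemble(
    config: SyntheticConfig,
    n_models: int = 9,
    target_corr: float | Sequence[float] = -0.8,
    noise_scale: float = 1.0,
) -> list[ModelBundle]:
    """Per-model (soil moisture, NEE, temperature) series with fixed coupling.

    Each model's water-NEE correlation is constant in time — the ensemble
    emulates simulations whose coupling is persistently high rather than
    strengthening.  ``target_corr`` may be scalar or per-model; with
    ``noise_scale=0`` the NEE-soil-moisture relation is exactly linear.
    """
    if n_models < 1:
        raise ValueError("need at least one model")
    corrs = np.broadcast_to(np.asarray(target_corr, dtype=float), (n_models,))
    rng = np.random.default_rng(config.seed + 17)
    years = config.years
    bundles = []
    for m in range(n_models):
        r = float(corrs[m])
        sm = rng.standard_normal(config.n_years)
        ortho = rng.standard_normal(config.n_years)
        nee = r * sm + noise_scale * np.sqrt(max(0.0, 1.0 - r ** 2)) * ortho
        temp = 0.3 * rng.standard_normal(config.n_years)
        bundles.append(
            ModelBundle(
                model_name=f"model_{m:02d}",
                soil_moisture=AnnualSeries(years, sm, units="kg m-2", name="soil_moisture"),
                nee=AnnualSeries(years, nee, units="PgC yr-1", name="nee"),
                temperature=AnnualSeries(years, temp, units="K", name="temperature"),
            )
        )
    return bundles
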
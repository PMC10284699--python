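import numpy as np
import pandas as pd
import pytest
import xarray as xr

import watercarbon as wc


def monthly_series(values, start="2000-01"):
    idx = pd.date_range(start, periods=len(values), freq="MS")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def make_field(values, lat=None, lon=None, time=None, units=""):
    """(time, lat, lon) DataArray from a plain array."""
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    if lat is None:
        lat = np.linspace(-20, 20, nlat)
    if lon is None:
        lon = np.linspace(0, 360, nlon, endpoint=False)
    if time is None:
        time = pd.date_range("2000-01-01", periods=nt, freq="MS")
    return xr.DataArray(
        values, coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"), attrs={"units": units},
    )


def make_yearly_field(values, years=None, lat=None, lon=None):
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    if years is None:
        years = np.arange(2000, 2000 + nt)
    if lat is None:
        lat = np.linspace(-20, 20, nlat)
    if lon is None:
        lon = np.linspace(0, 360, nlon, endpoint=False)
    return xr.DataArray(
        values, coords={"year": years, "lat": lat, "lon": lon},
        dims=("year", "lat", "lon"),
    )


@pytest.fixture(scope="session")
def study_ds():
    """One mid-size synthetic study dataset shared across tests."""
    return wc.generate_study_dataset(wc.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def study_bundle(study_ds):
    return wc.observational_bundle(study_ds)
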
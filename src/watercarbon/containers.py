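"""Core data containers shared by all pipeline stages.

Gridded monthly/yearly fields are held as :class:`xarray.DataArray` objects
with dims ``("time", "lat", "lon")`` and a ``units`` attribute; a land /
vegetation mask travels alongside as a boolean ``(lat, lon)`` DataArray.
Scalar year-indexed quantities (CO2 growth rate, tropical aggregates) use
:class:`AnnualSeries`, which carries an explicit per-year validity flag so
that excluded years (volcanic perturbations, incomplete coverage) propagate
through every downstream statistic instead of being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import xarray as xr

__all__ = [
    "AnnualSeries",
    "BootstrapResult",
    "SensitivityEstimate",
    "EnsoCalendar",
    "CoherenceSeries",
    "EofResult",
    "ModelBundle",
    "AgcCalibration",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but statistically degenerate
    (zero variance, too few valid years, empty mask, collinear control)."""


@dataclass
class AnnualSeries:
    """A year-indexed scalar series with units and a validity mask.

    Parameters
    ----------
    years : array of int
        Strictly increasing calendar years.
    values : array of float
        One value per year.  Values of invalid years are kept (they may be
        computable) but are excluded from every downstream statistic.
    valid : array of bool, optional
        Defaults to all-valid.
    units : str
        Physical units of ``values``.
    name : str
        Variable name, used in tables and error messages.
    """

    years: np.ndarray
    values: np.ndarray
    valid: np.ndarray | None = None
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.years.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.years.ndim != 1:
            raise ValueError("years must be 1-D")
        if not (self.values.shape == self.years.shape == self.valid.shape):
            raise ValueError("years, values and valid must have equal length")
        if self.years.size > 1 and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")

    def __len__(self) -> int:
        return self.years.size

    def copy(self) -> "AnnualSeries":
        return AnnualSeries(
            self.years.copy(), self.values.copy(), self.valid.copy(),
            units=self.units, name=self.name,
        )

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def valid_years(self) -> np.ndarray:
        return self.years[self.valid]

    def subset(self, start: int, end: int) -> "AnnualSeries":
        """Restrict to calendar years ``start <= y <= end`` (inclusive)."""
        sel = (self.years >= start) & (self.years <= end)
        if not sel.any():
            raise ValueError(f"window [{start}, {end}] outside data span")
        return AnnualSeries(
            self.years[sel], self.values[sel], self.valid[sel],
            units=self.units, name=self.name,
        )


def align_series(*series: AnnualSeries) -> tuple[np.ndarray, list[np.ndarray]]:
    """Intersect several annual series on jointly valid years.

    Returns the shared years and the list of value arrays restricted to
    years present and valid in every input.
    """
    common = series[0].years[series[0].valid]
    for s in series[1:]:
        common = np.intersect1d(common, s.years[s.valid])
    out = []
    for s in series:
        idx = np.searchsorted(s.years, common)
        out.append(s.values[idx])
    return common, out


@dataclass
class BootstrapResult:
    """Replicate values of a statistic with a percentile confidence interval."""

    statistic_name: str
    replicates: np.ndarray
    point_estimate: float
    ci: tuple[float, float]
    n_reps: int
    seed: int
    level: float = 0.95

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.size != self.n_reps:
            raise ValueError("replicates length must equal n_reps")
        if self.ci[0] > self.ci[1]:
            raise ValueError("ci bounds out of order")

    def covers(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]


@dataclass
class SensitivityEstimate:
    """A regression slope of CGR on a climate driver, with uncertainty.

    ``gamma`` carries the units implied by its inputs, e.g. PgC yr-1 per
    Tt H2O for a water-storage predictor or PgC yr-1 per K for temperature.
    """

    gamma: float
    model_kind: Literal["univariate_ols", "bivariate_ridge", "bivariate_ols"]
    regularization: float = 0.0
    bootstrap: BootstrapResult | None = None
    predictor: str = ""

    def __post_init__(self) -> None:
        if self.model_kind == "univariate_ols" and self.regularization != 0.0:
            raise ValueError("univariate OLS has no regularization")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


EP = "EP"
CP = "CP"
NEUTRAL = "NEUTRAL"


@dataclass
class EnsoCalendar:
    """Per-year ENSO-type labels plus the index values that produced them.

    A year is EP when the largest equatorial DJF SST anomaly sits east of
    150 W and the Nino3 DJF anomaly exceeds one standard deviation; CP when
    the peak sits west of 150 W and Nino4 exceeds one standard deviation;
    NEUTRAL otherwise.  Labels are mutually exclusive.
    """

    years: np.ndarray
    labels: np.ndarray  # str array in {EP, CP, NEUTRAL}
    nino3: np.ndarray
    nino4: np.ndarray
    nino34: np.ndarray
    peak_longitude: np.ndarray  # degrees east, NaN where undefined
    valid: np.ndarray
    notes: dict[int, str] = field(default_factory=dict)

    def label_of(self, year: int) -> str:
        i = int(np.searchsorted(self.years, year))
        if i >= self.years.size or self.years[i] != year:
            raise KeyError(year)
        return str(self.labels[i])


@dataclass
class CoherenceSeries:
    """Per-year spatial coherence (percent) with tercile bin labels.

    Bins partition the valid years at the 33.3rd and 66.6th percentiles of
    the coherence values: LOW below the first, HIGH above the second.
    """

    years: np.ndarray
    coherence: np.ndarray  # percent, in [-100, 100]
    bins: np.ndarray  # str array in {LOW, MEDIUM, HIGH}; "" where invalid
    valid: np.ndarray


@dataclass
class EofResult:
    """Orthogonal spatial modes of a gridded anomaly field.

    ``patterns[k]`` is a (lat, lon) map, ``pcs[k]`` the matching per-year
    series; explained variance fractions are non-increasing and sum to at
    most one.
    """

    patterns: list[xr.DataArray]
    pcs: list[AnnualSeries]
    explained_variance: np.ndarray


@dataclass
class ModelBundle:
    """Prepared tropical-aggregate series from one model simulation."""

    model_name: str
    soil_moisture: AnnualSeries
    nee: AnnualSeries
    temperature: AnnualSeries
    soil_moisture_grid: xr.DataArray | None = None


@dataclass
class AgcCalibration:
    """Fitted parameters of the saturating arctan VOD-to-AGC mapping."""

    a: float
    b: float
    c: float
    d: float
    inf_const: float = 1.0e10
    fit_r2: float = float("nan")
    n_cells: int = 0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)
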
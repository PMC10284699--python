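"""End-to-end convenience layer tying the pipeline stages together."""

from __future__ import annotations

import numpy as np

from .containers import AnnualSeries
from .preprocess import (
    annual_cgr_from_monthly_co2,
    area_weighted_tropical_mean,
    detrend_linear,
    exclude_volcano_years,
    lagged_annual_precip,
)
from .synthetic import StudyDataset

__all__ = ["observational_bundle"]


def observational_bundle(
    ds: StudyDataset,
    volcano_years: frozenset[int] | set[int] = frozenset(),
    detrend: bool = False,
) -> dict[str, AnnualSeries]:
    """Annual CGR, tropical water, temperature and LagP from a study dataset.

    Validity flags are harmonized across the four series (a year invalid
    anywhere — e.g. the first year, which supports neither a CGR
    difference nor a complete lagged-precipitation window — is invalid
    everywhere), so detrending and statistics see identical year sets.
    With ``detrend=True`` each series is detrended over its full valid
    span; leave False when downstream windows re-detrend.
    """
    cfg = ds.truth["config"]
    cgr = annual_cgr_from_monthly_co2(ds.co2_monthly, ppm_to_pgc=cfg.ppm_to_pgc)
    water = area_weighted_tropical_mean(ds.ws, mask=ds.veg_mask, mode="sum_Tt")
    temp = area_weighted_tropical_mean(
        ds.temp, mask=ds.veg_mask, mode="mean", units="K", name="T"
    )
    lagp = lagged_annual_precip(ds.precip, mask=ds.veg_mask)

    bundle = {"cgr": cgr, "water": water, "temp": temp, "lagp": lagp}
    if volcano_years:
        bundle = {k: exclude_volcano_years(s, volcano_years) for k, s in bundle.items()}

    joint = np.ones(cgr.years.size, dtype=bool)
    for s in bundle.values():
        joint &= s.valid
    for s in bundle.values():
        s.valid = joint.copy()
    if detrend:
        bundle = {k: detrend_linear(s) for k, s in bundle.items()}
    return bundle
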
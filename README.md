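# watercarbon

Tools for analysing the interannual coupling between tropical terrestrial
water availability and the atmospheric CO₂ growth rate (CGR), and how that
coupling changes over decades.

The interannual variability of the atmospheric CO₂ growth rate is set
largely by the tropical land carbon sink, which responds to both
temperature and water availability. Whether the *aggregated* tropical
water anomaly matters for a given year depends on its spatial structure:
spatially coherent anomalies (one sign across the tropics, typical of
ENSO years) add up, while compensating wet/dry dipoles cancel. This
package implements that analysis chain as a reusable, tested pipeline:

* **preprocess** — annual CGR from monthly CO₂ (December-minus-December
  rule, ppm → PgC yr⁻¹ with 2.124 PgC ppm⁻¹), linear detrending on valid
  years, volcanic-year exclusion (1963–64, 1982, 1991–93), cos-latitude
  tropical aggregation (24° S–24° N), and six-month-lagged yearly
  precipitation (LagP, July–June sums).
* **coupling_stats** — Pearson and partial correlations
  (r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))), case bootstrap
  (5 000 replicates, percentile CIs), change-of-coupling significance
  from paired replicate differences, univariate OLS sensitivities
  (γ_WS in PgC yr⁻¹ per Tt H₂O), and bivariate ridge sensitivities with
  the penalty chosen by 25 random train/validation splits over 100
  log-spaced values; fixed-window and 25-year moving-window analyses
  with per-window re-detrending.
* **enso** — Niño3/Niño4/Niño3.4 DJF indices and per-year EP/CP/neutral
  typing: EP when the peak equatorial DJF SST anomaly (2° S–2° N,
  110° E–90° W) lies east of 150° W and Niño3 exceeds 1 s.d.; CP when it
  lies west and Niño4 exceeds 1 s.d.
* **coherence** — the spatial-coherence statistic
  100·(tcov⁺ + tcov⁻)/tcov over off-diagonal cell-pair covariances
  (blockwise, the full matrix is never materialised), its per-year
  closed form, coherence terciles, and tercile-conditioned coupling.
* **model_diag** — the same coupling metrics applied to model ensembles
  (soil moisture vs. NEE), with box-plot summary statistics, plus EOF
  decomposition of gridded anomalies (√cos-lat weighting).
* **vod_agc** — the four-parameter saturating arctan calibration from
  vegetation optical depth to aboveground carbon and the semi-arid
  AGC–CGR coupling.
* **synthetic_data** — a seeded generator producing every input the
  pipeline consumes (monthly CO₂, gridded water storage / precipitation /
  temperature / SST, masks, model ensembles, VOD–AGC pairs) with known
  ground truth, so the whole chain is testable without downloads.

## Worked example

A two-era experiment: a neutral-dominated first era against a second era
enriched in Central-Pacific ENSO events.

```python
import numpy as np
import watercarbon as wc
from watercarbon.coupling import window_corr_bootstrap, change_significance
from watercarbon.coherence import yearly_coherence, coherence_fraction
from watercarbon.preprocess import annualize_field, detrend_linear

years = np.arange(1959, 2019)
schedule = wc.regime_schedule(years, break_year=1989, seed=1)
cfg = wc.SyntheticConfig(years_start=1959, years_end=2018, seed=1,
                         enso_schedule=schedule)
ds = wc.generate_study_dataset(cfg)
bundle = wc.observational_bundle(ds)

era1, era2 = (1960, 1989), (1989, 2018)
r1 = window_corr_bootstrap(bundle["water"], bundle["cgr"], era1, n_reps=5000, seed=0)
r2 = window_corr_bootstrap(bundle["water"], bundle["cgr"], era2, n_reps=5000, seed=1)
delta, p = change_significance(r1, r2)

anom = detrend_linear(annualize_field(ds.ws).rename(year="time")).rename(time="year")
cs = yearly_coherence(anom, mask=ds.veg_mask)
print(f"R(WS, CGR) {era1}: {r1.point_estimate:+.2f} [{r1.ci[0]:+.2f}, {r1.ci[1]:+.2f}]")
print(f"R(WS, CGR) {era2}: {r2.point_estimate:+.2f} [{r2.ci[0]:+.2f}, {r2.ci[1]:+.2f}]")
print(f"change in correlation: {delta:+.2f} (bootstrap p = {p:.3f})")
print(f"high-coherence fraction: {coherence_fraction(cs, era1):.2f} -> "
      f"{coherence_fraction(cs, era2):.2f}")
```

prints

```
R(WS, CGR) (1960, 1989): +0.14 [-0.20, +0.49]
R(WS, CGR) (1989, 2018): -0.90 [-0.94, -0.84]
change in correlation: -1.04 (bootstrap p = 0.000)
high-coherence fraction: 0.00 -> 0.67
```

The water–CGR correlation is indistinguishable from zero while tropical
water anomalies are spatially compensating, turns strongly negative once
ENSO events make them coherent, and the change is significant under the
paired-bootstrap test. The tercile-based high-coherence fraction rises
accordingly. (Across seeds these directions are systematic; see
`tests/test_acceptance.py`.)

The same stages are scriptable from a shell:

```sh
watercarbon synth --seed 3 --out run/
watercarbon prep --in run/ --out run/series.csv
watercarbon enso --in run/ --out run/enso.csv
watercarbon coherence --in run/ --out run/coherence.csv
watercarbon couple --in run/ --out run/coupling.csv
```

## Documentation

`docs/methods.md` describes the statistical model behind the synthetic
generator, every tunable parameter with units and defaults, the
numerical conventions (detrending order, DJF labelling, tie-breaks,
degenerate inputs), and the known limitations of the synthetic study
design.
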
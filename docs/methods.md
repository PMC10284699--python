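# Methods

## The analysis in brief

The pipeline quantifies how strongly the interannual variability (IAV)
of the atmospheric CO₂ growth rate (CGR) is coupled to tropical
terrestrial water availability, how that coupling differs between
periods, and what role the *spatial structure* of water anomalies plays.
All statistics operate on detrended annual anomalies over vegetated
tropical land (24° S–24° N), with years perturbed by major volcanic
eruptions (1963–64, 1982, 1991–93 by default) excluded.

### CGR and the annual series

The growth rate of year *y* is the CO₂ concentration increase across
that calendar year. On monthly data the operational rule is
December(y) − December(y−1) of monthly means; the first year of a record
is therefore flagged invalid rather than extrapolated. An
`annual_mean_diff` strategy (difference of calendar-year means) is
provided as a sensitivity option. Conversion to carbon mass uses
2.124 PgC per ppm (configurable; a standard airborne-mass convention —
tests can set it to 1).

Tropical aggregates are cos-latitude-weighted means (temperature), or
area-integrated mass sums in Tt H₂O (water storage), so that
sensitivities carry PgC yr⁻¹ per Tt H₂O and PgC yr⁻¹ per K. An
unweighted mode exists because equal-cell weighting is a plausible
alternative convention. LagP — the July(y−1)–June(y) precipitation sum —
serves as an observationally independent proxy for the aggregated water
anomaly (soil-water memory delays the imprint of rainfall on storage).

Detrending removes the ordinary-least-squares line fitted **on valid
years only**, so an excluded outlier year cannot tilt the trend; the
anomaly of an invalid year is still computed but stays flagged. Windowed
analyses re-detrend inside each window by default (each window's
statistic then reflects IAV about its own trend); full-period detrending
is available as a flag because the choice is genuinely open for the
fixed two-window comparison.

### Coupling statistics

Correlation uncertainty and change significance use a case bootstrap:
years are resampled jointly across all series (preserving
cross-variable dependence), 5 000 replicates, percentile intervals.
Degenerate replicates (zero variance after resampling) are redrawn with
a cap of 10× the replicate count. The significance of a change between
two independently bootstrapped periods is
p = min(1, 2·min(Pr(Δ\* ≥ 0), Pr(Δ\* ≤ 0))) over paired replicate
differences Δ\*.

Partial correlations use the first-order recursion, which is
algebraically identical to correlating the OLS residuals after removing
the control variable; the equivalence is enforced by test to 10⁻¹².
Correlation p-values use the two-sided t approximation
(df = n − 2 − #controls).

The bivariate sensitivity of CGR to water and temperature uses ridge
regression because the two predictors are collinear (both respond to
ENSO). Predictors are standardized; the penalty is selected by 25
random 75/25 train/validation splits, each picking the best of 100
log-spaced values in [10⁻⁴, 10²] by validation MSE, and averaging the
winners (all counts and the range configurable). Coefficients are
rescaled to original units; uncertainty comes from the case bootstrap
at the selected penalty. A penalty-free bivariate OLS mode is kept for
cross-checks — note that ridge shrinkage is a *deliberate bias*, so
percentile CIs of the ridge estimator are not expected to attain
nominal coverage of the true coefficients; unbiased-coverage checks use
the OLS mode, while ridge correctness is pinned by exact λ → 0 and
closed-form identities.

### ENSO typing

Niño indices are area-weighted box means of SST anomalies relative to a
per-cell, per-calendar-month climatology (window configurable;
removing a monthly climatology makes the classification invariant to
any uniform SST offset). DJF of year *y* is December(y−1)–February(y);
a year lacking any of the three months is invalid. Box definitions:
Niño3 5° N–5° S, 150° W–90° W; Niño4 5° N–5° S, 160° E–150° W; Niño3.4
5° N–5° S, 120° W–170° W — the conventional boundaries, since only
Niño3.4's box is non-standard enough to need stating. A year is EP when
the largest DJF anomaly in the 2° S–2° N, 110° E–90° W scan band lies
east of 150° W **and** Niño3 strictly exceeds one standard deviation of
its own DJF series over the climatology window; CP mirrors this west of
150° W with Niño4. Exceedance is strict, so a value exactly at the
threshold is neutral. When the peak side and the exceeding index
disagree (e.g. peak east but only Niño4 exceeds) the year is labelled
NEUTRAL and a note is recorded — the rule is otherwise silent and this
convention is surfaced to the user. SST anomalies are not detrended
before classification by default; a flag enables it.

### Spatial coherence

For cell-pair covariances c_ij over a period, coherence =
100·(tcov⁺ + tcov⁻)/tcov with tcov = Σ_{i≠j} |c_ij|; diagonal variances
are excluded (always positive, no coherence information). The sums are
accumulated blockwise so the cells×cells matrix is never held in
memory. The per-year variant applies the same pairwise form to a single
year's anomaly map x via the O(cells) closed form
100·[(Σxᵢ)² − Σxᵢ²]/[(Σ|xᵢ|)² − Σxᵢ²], i.e. the year's own
outer-product contribution to the covariance sums — the natural
single-year restriction of the per-period definition, and the one with
a clean pairwise-loop oracle. Zero-anomaly cells contribute nothing (no
sign is assigned); a year with fewer than two nonzero cells is invalid.
Optional area weighting multiplies pair terms by cos(latᵢ)cos(latⱼ);
the default is unweighted, matching the bare covariance definition.
Terciles (LOW/MEDIUM/HIGH at the 33.3/66.6 percentiles) are assigned
jointly over the full valid record so window fractions are comparable;
per-window tercile assignment is available.

### Model diagnosis and EOF

Model bundles (tropical soil moisture, NEE, temperature) pass through
exactly the same correlation/partial/sensitivity code path as the
observations; window defaults are 1960–1986 and 1988–2014. Ensemble
summary rows report median, interquartile range and 5th–95th
percentiles. NEE follows the respiration-minus-photosynthesis sign
convention (sink negative); correlations are stored as computed. EOF
modes come from the SVD of the √cos(lat)-weighted time×cells anomaly
matrix; patterns are returned in physical units with the
largest-magnitude loading forced positive, and retaining all modes
reconstructs the field to numerical tolerance.

### VOD → AGC

AGC = a·[arctan(b(VOD−c)) − arctan(−bc)] / [arctan(b(Inf−c)) −
arctan(−bc)] + d with Inf = 10¹⁰; monotone non-decreasing for b > 0,
saturating at a + d. Fitting uses nonlinear least squares with a
deterministic multi-start (a ≈ range(AGC), d ≈ min(AGC),
c ≈ median(VOD), b ∈ {0.5, 1, 5}) — robust for a saturating curve whose
curvature scale is unknown a priori; the best start by residual sum of
squares wins and R² is reported. A benchmark supplied as biomass is
halved to carbon by the documented helper. The semi-arid domain is the
shrubland + savannah land-cover classes; its AGC aggregate is coupled
to CGR either through year-to-year *changes* (a flux proxy; default) or
detrended *levels* — both modes exist because the flux-vs-level choice
is genuinely open.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not the physics. Per year:

* a scripted ENSO calendar assigns EP/CP/NEUTRAL; event strength
  e_y = A·(1 + 0.2|N(0,1)|) with A = `enso_amplitude_sd` (default 2);
* water-storage anomalies load on a one-signed **coherent pattern** in
  event years (aggregate −e_y Tt: El Niño droughts) and on an
  area-compensating zonal **dipole** plus independent cell noise
  (`ws_cell_noise_sd`, default 0.25 of the pattern RMS) in neutral
  years; the coherent pattern is normalised so unit loading aggregates
  to exactly 1 Tt H₂O;
* temperature anomalies are `temp_enso_coef`·e_y (0.15 K per strength
  unit) plus independent noise (`temp_noise_sd` = 0.15 K), making water
  and temperature collinear through ENSO, as observed;
* CGR_y = γ_WS·W_y + γ_T·T_y + ε, ε ~ N(0, `noise_sd_cgr` = 0.5
  PgC yr⁻¹), on a linear trend, where W_y and T_y are the *actual*
  area-aggregated anomalies computed with the pipeline's own
  aggregator — the truth record is exactly self-consistent. Defaults
  γ_WS = −1 PgC yr⁻¹ per Tt H₂O and γ_T = 2 PgC yr⁻¹ per K are of the
  magnitude expected for tropical interannual sensitivities;
* monthly CO₂ integrates CGR (ppm) between Decembers, so the
  December-difference rule inverts the generator to rounding error; the
  optional seasonal cycle (default amplitude 0) cancels in
  December-to-December differences by construction;
* precipitation distributes each year's aggregate water anomaly over
  its July–June window, so LagP tracks the water aggregate exactly;
* SST is a deterministic monthly climatology plus DJF anomaly blobs at
  120° W (EP) or 175° E (CP), scaled so the box-averaged index exceeds
  the 1 s.d. threshold of the resulting index series at realistic event
  fractions. Cell noise defaults to zero: the all-neutral field then
  carries exactly zero anomalies, which is the only construction under
  which "no events ⇒ no labels" holds deterministically (any index
  noise puts ~16 % of neutral years beyond 1 s.d. of their own series).
  Round-trip tests switch noise on explicitly.

The default span 1959–2018 yields 59 analysable years (the first year
supports neither a CGR difference, a LagP window, nor a DJF season).

`regime_schedule` builds the two-era experiment: an event-free first
era and a second era with 10 % EP + 40 % CP years (deterministic
composition, seeded ordering). The first era is fully neutral because
generated events all share the same fully coherent land imprint — even
two or three of them saturate the era's water–CGR correlation — so an
event-free era is the cleanest way to encode "weak early coupling"
under this simplification.

### What the generator does *not* emulate

Realistic ENSO dynamics and event diversity (all events imprint the
same land pattern), GRACE-style measurement error and trend artefacts,
station-density effects in precipitation, spatially heterogeneous
temperature responses, lagged or asymmetric carbon-cycle responses, and
non-ENSO drivers of coherent water anomalies (Atlantic, Indian-Ocean
variability). Passing tests therefore demonstrate that the *estimators
and their contracts* behave correctly under the assumed statistical
structure — not that the structure captures every property of the real
observational datasets.

## Numerical conventions and degenerate inputs

* Detrending requires ≥3 valid points; correlations ≥3 jointly valid
  years (partials ≥4, bivariate fits ≥6); violations raise a
  degenerate-input error rather than returning NaN.
* Exactly collinear inputs: partial correlation and bivariate OLS
  refuse; ridge proceeds with a warning (the penalty splits the
  effect).
* Coherence with all pairwise covariances zero is undefined and
  raises; a tercile bin smaller than 5 years is reported as undefined
  (NaN) instead of raising, since neighbouring bins remain meaningful.
* Bootstrap seeds: every stochastic routine takes an explicit integer
  seed and is bit-reproducible; the generator's truth record plus seed
  reproduces every series exactly.
* Test problem sizes: the shipped suite runs the full-pipeline checks
  on 12×24-cell tropical grids, 56–60-year records, 5 000 bootstrap
  replicates, and 50–100 seeded repetitions of the simulation
  experiments — small enough to iterate on while large enough for the
  asserted coverage and power margins.

## Known limitations

* The per-year coherence is a closed-form restriction of the
  per-period pairwise definition; other single-year reductions are
  conceivable and would order years slightly differently near the
  tercile boundaries.
* Percentile bootstrap CIs at n ≈ 30–55 undercover mildly (~92–93 % at
  nominal 95 %); the acceptance margins account for this.
* "No spurious trend detection" on stationary data is operationalised
  as overlap of the two windows' 95 % bootstrap CIs plus across-seed
  flatness of the moving-window mean; a raw p < 0.1 rule would by
  definition flag ~10 % of null cases.
* The EP/CP tie rule (peak side vs. exceeding index disagreeing →
  NEUTRAL with a note) is a convention, flagged in the classifier
  output.
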
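# Methods

This note documents the model, the choices behind its defaults, what the
synthetic-data generators do and do not emulate, and the numerical details
a user re-tuning the package should know.  It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Density module

The latewood-density response is the symmetric four-parameter logistic
`LWD(T) = a + (b − a)/(1 + exp(−c(T − d)))` of the JAS (July–September)
mean temperature.  The parameter roles — lower/upper asymptote, growth
rate, midpoint — identify this form uniquely; the generalised-Richards
asymmetry exponent is fixed at 1 because nothing in the calibration data
at desk scale constrains a fifth parameter.

Total ring density composes as `TRD = f_ew·EWD + (1 − f_ew)·LWD` with
`f_ew = 0.70` and `EWD = 139 kgC/m³`.  The 70:30 split is applied to the
ring's **volume** contribution (and hence to the carbon of the annual
volume increment).  Applying it by ring width instead would require an
intra-ring geometry model; for a cylindrical shell the two interpretations
differ only by a second-order term in the width, so the volume reading was
chosen and exposed as a single fraction.

Unit conversions (0.828 air-dry → oven-dry, 0.5 carbon fraction) are
applied to input densities **before** outlier screening and fitting, so
all downstream math lives in kgC/m³.  The lapse adjustment is
`T_site = T_gridcell − 0.649·Δelev/100` with Δelev = site − reference
elevation: sites above their gridcell reference are cooler, the standard
environmental-lapse convention.

## Fitting pipeline

* Site-year aggregation is an unweighted mean over trees.
* Outlier screening uses |z| > 3 with the **population** standard
  deviation, computed once on the full series (single pass, no
  re-iteration), applied **per site**.  A constant series passes through
  unchanged.  Note a small-sample subtlety the tests exercise: with nine
  identical values and one deviant, |z| is exactly 3 whatever the spike
  size, so the strict rule keeps it; the cut only engages in larger or
  less degenerate samples.
* The window search scans all contiguous 1–4-month windows within
  April–October and maximises the R² of the pooled linear regression of
  density on window-mean temperature.  Ties keep the earlier candidate.
* Binning uses half-open intervals `[k·w, (k+1)·w)` anchored at 0 °C,
  width 0.5 °C; fitting uses the **unweighted** bin means (binning exists
  precisely to de-weight data-dense temperatures).
* The logistic fit is multi-start Levenberg–Marquardt (scipy
  `curve_fit`): asymptote and midpoint starts come from data quantiles
  (5%/95% of bin means; the bin nearest the half-range and the median
  temperature), crossed with growth-rate starts {0.1, 0.5, 1, 2, 5}; the
  converged start with the lowest SSE wins, constrained to a ≤ b, c ≥ 0.
  On a frozen noisy fixture the result agrees with R's
  `minpack.lm::nlsLM` to ~1e−5 relative (see `tests/test_fitting.py`).
* The range variant rounds the observed extremes to 1 kgC/m³ (the
  rounding unit is configurable), copies the midpoint exactly and re-fits
  only the growth rate.

## Demography

A cohort is one *average individual* plus a stem density (individuals per
m²); the experiments use a single replanted cohort per patch.  Annual
order of operations: productivity → leaf/root turnover → reproduction
(10% of NPP) → ring density for the year → allocation → sapwood-to-
heartwood transfer (5%/yr of sapwood carbon and area) → self-thinning.

**Stand-in productivity.**  NPP = p0 × leaf area × exp(−((T −
T_opt)/T_w)²) × mean Beer–Lambert light availability over the patch LAI
(k = 0.5) × lognormal patch noise (2% by default).  This replaces daily
photosynthesis/hydrology: it keeps the two drivers the cascade needs
(temperature, light competition) and nothing else.  Defaults p0 =
0.55 kgC/m² leaf/yr, T_opt = 12 °C, T_w = 10 °C were chosen once so that a
mid-gradient stand closes its canopy after ~60 years and reaches ~25 m at
year 100 — ordinary values for planted spruce — and are not re-tuned
anywhere.

**Allocation.**  Height and crown area are power laws of diameter
(40·D^0.67 m, 150·D^1.6 m² capped at ca_max); stem volume is cylindrical;
leaf area is tied to sapwood cross-section by the pipe model (k_latosa =
3000, SLA = 9.3 m²/kgC, fine roots 1:1 with leaves).  The year's diameter
increment solves `TRD·ΔV(ΔD) + Δleaf(ΔD) + Δroot(ΔD) = growth carbon` by
bisection.  The **entire** annual volume increment — radial shell plus the
height extension — is priced at the current year's ring density, because
the year's density is a property of the newly forming wood wherever it is
laid down; pricing only the shell at the new density would need an
explicit stem-taper model to say which volume is "new height".  When even
a zero-width ring cannot cover the pipe-model leaf/root deficits, the
carbon goes to leaves and roots in proportion to their deficits and the
ring width is zero (recorded as such).

**Crown cap.**  ca_max defaults to 80 m².  With the experiment's fixed
replanting density of 200 trees/ha (0.02 /m²), a cap at 50 m² would make
summed crown area asymptote to exactly 1.0 and crowding mortality could
never engage; 80 m² keeps closure attainable with crowns below the cap so
self-thinning stays operational.  Mortality is the crowding rule only
(background and growth-efficiency mortality default to zero), which is
what makes tree counts provably identical across density modes until
closure.

**Bookkeeping invariants** (tested): ring widths sum to the radius; ring
carbons sum to sapwood + heartwood (no heartwood decay); each ring's
carbon equals its density × volume; the annual carbon budget NPP =
Δcompartments + turnover + reproduction closes to ≤1e−9 relative in every
simulated year of the full gradient run (measured ~2e−13).  Whole-stem
density (SWD) is total ring carbon over total ring volume; sapwood density
is the volume-weighted density of the three most recent rings.

**One code path.**  All stepping is written as vectorised "lane"
primitives; the `Cohort`/`Patch` objects run them on single lanes and the
experiment engine on member×patch blocks, so the scalar and ensemble paths
cannot drift apart (tested to 1e−12).

## Experiments

Recovery: bare-ground replanting at 200 trees/ha, 300 years, 5 sites,
30 members, 25 patches, three modes (static, dynamic-best,
dynamic-range).  There is no spin-up: only the replanted cohort is
simulated and the simplified model carries no soil or legacy state; a
spin-up would be a no-op.  Member k enters the repeating 30-year cycle at
offset k.  Reported series are patch means first, ensemble statistics
second.  Relative differences are member-matched (each dynamic member
against the static member sharing its climate offset and noise), which
removes ensemble sampling noise from the comparison; a zero baseline
yields NaN, never a silent drop.

Warming: per site, one representative member (lowest RMSE of its canopy
series against the ensemble mean, ties to the lowest index, selected in
the first dynamic mode) is re-run with a uniform all-month +2 °C step
switched on the year after a canopy-fraction stage (0.10 / 0.50 / 0.90 /
1.00 by default) is first reached.  Stages a site never reaches are
skipped with a logged warning.

## Synthetic data

The climate generator builds one stochastic 30-year monthly cycle per
site — a cosine seasonal course peaking in July (amplitude 8 °C) plus
white monthly noise (sd 1.2 °C) — shifts it so the cycle-mean JAS
temperature equals the site's target exactly, and tiles it; warming adds a
uniform step.  The default gradient places five sites so their composed
equilibrium TRD brackets the 186 kgC/m³ baseline: coldest below, hottest
above, the middle site at the response midpoint (within ±2 kgC/m³).  The
ring-density generator draws per-tree values from the response at the
actual JAS mean plus Gaussian noise (10 kgC/m³ default).

What this does **not** emulate: observed climates (no reanalysis input),
precipitation/radiation/CO₂, autocorrelated or trending climate,
species mixtures, establishment, and the absolute magnitudes a full
vegetation model produces.  Passing tests therefore demonstrate the
internal consistency and the *direction* of the density–demography
cascade under controlled conditions, not quantitative fidelity to any
observed forest.

## Validation studies and problem sizes

`parameter_recovery_study` (100 datasets of 5 sites × 99 years × 10
trees, noise 10 kgC/m³) checks the fit recovers the generating midpoint
to ≤0.5 °C and the upper asymptote to ≤5% in the median; measured medians
are ~0.02 °C and ~0.1%.  `window_recovery_study` uses single-site
500-year series with noise calibrated to a population R² of 0.34 — a
realistic signal strength for this proxy — and requires the JAS window to
win ≥95% of 100 trials; a pooled multi-site fixture would let the shared
site-mean gradient inflate every candidate window's R² and blur the
comparison, so the study isolates the interannual signal.  The full
gradient run (5 × 3 × 30 × 25 × 300 years) executes in well under a
minute via the lane engine; the acceptance script completes in about half
a minute.

## Known limitations

Single species, single cohort, no nitrogen/water limitation, no daily
physiology, no heartwood decay, crowding-only mortality, fixed earlywood
fraction and density (the known first-order bias: real EW:LW ratios vary
with climate), and a productivity stand-in whose constants are
order-of-magnitude choices.  The package is built to expose the density
cascade cleanly, not to reproduce any particular forest inventory.
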
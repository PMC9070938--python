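# Methods

## The model

The quantity of interest is the annual summer canopy extent of bull kelp,
*E_y* (km²), per region (north and south of Point Arena, 39°N). The working
hypothesis is that *E_y* is set by ocean conditions in the seasons before
the summer peak — above all winter, when the overwintering gametophyte
stage is in the water. Each candidate model is a univariate linear
regression

  E_y = α + β·x_y + ε_y,  ε_y ~ N(0, σ²) i.i.d.,

where *x_y* is one environmental index averaged over one season aligned to
kelp year *y*: fall is October–December of *y − 1*; winter, spring and
summer are JFM, AMJ and JAS of *y*. Warm, downwelling-favourable phases
correspond to low nutrients, so β is expected negative for MOCI- and
SST-type predictors.

Inference is deliberately plain: the slope t-test with n − 2 degrees of
freedom, significance at α = 0.05 per cell, no autocorrelation correction
and no multiple-testing adjustment across the screen. The last two are
caveats, not oversights: the annual series are short (≤ 23 complete years)
and the screen is read as a ranking device, with model choice delegated to
AIC among significant candidates. The AIC convention is pinned to the full
Gaussian maximum likelihood form, AIC = n·ln(2π·SSE/n) + n + 2k with k = 2;
only differences at equal n are meaningful, and a perfect fit (SSE = 0)
maps to −∞ so it sorts first. Ties on AIC break toward higher R², then
lexicographic index name, making selection deterministic and
order-independent.

## Canopy quality control

A satellite pixel with no value is *missing*, not zero: cloud cover and
zero kelp are indistinguishable in the imagery, and treating gaps as zeros
would bias extents low exactly in cloudy (often stormy, low-kelp) years.
The QC chain therefore works on 0.1° latitude bands:

* a band-year's data count below `qc_fraction` (default 0.90) of that
  band's median count across observed years is flagged missing — strictly
  below, so a count exactly at 90% of the median survives;
* the band median uses the mean-of-middle-two convention for even counts,
  and is taken over the years in which the band has any data;
* a region-year whose flagged fraction of active bands exceeds `tolerance`
  (default 0.10) is missing; otherwise the regional extent is the sum over
  unflagged bands × 10⁻⁶ km²/m².

Two interpretation choices were genuinely open and are resolved as follows.
The 10% missing-data rule is applied to the fraction of flagged *bands*
(the unit the preceding QC step operates on), not pixels. Flagged bands
inside an accepted year are excluded without infilling or rescaling, which
slightly underestimates the regional extent; the alternative (rescaling by
the missing weight) would silently assume kelp density is uniform across
bands, which the band-weight structure of real canopies contradicts.

All intervals are half-open [low, high): 39.00°N belongs to the north
region, and a 1e-9° snap before flooring keeps decimal band edges (38.1,
39.0) in the mathematically correct band despite binary floating point.

## Seasonal predictors

A seasonal mean requires all three months; any absent month makes the
season missing. With 3-month windows a partial mean is badly biased toward
whichever months survive, and no principled fill rule exists at this
resolution. Pairing for regression is complete-case per (kelp, predictor)
combination, ascending in year; fits refuse fewer than 3 pairs,
leave-one-out fewer than 4.

## Leave-one-out statistics

"Precision" is the mean of the *in-sample* R² of each leave-one-out refit,
not a predictive R²: for stable models these match the full-period R²
almost exactly, and that agreement is itself a useful stability diagnostic.
The predictability error |y − ŷ|/|y| × 100 keeps raw denominators — a small
observed extent legitimately produces triple-digit percentages, which is
precisely the behaviour that makes the post-collapse years stand out. Only
y = 0 leaves the error undefined; such years are flagged, warned about and
excluded from the aggregates.

## Forecasting and the leakage guard

Forecast models are trained strictly on years before the split (default
2014). Raw predictions may be negative; the percent error is computed from
the raw value (clipping first would understate misses below zero), and a
zero-clipped column is reported alongside because extent is physically
nonnegative. Any overlap between training years and forecast years raises
an error rather than silently leaking.

## The synthetic generator

The generator emulates the statistical structure of the study inputs, not
their oceanography:

* **Indices** — zero-mean unit-variance AR(1) monthly latents (default
  φ = 0.6, a moderate month-to-month persistence typical of large-scale
  ocean indices; `phi_for_adjacent_season_corr` inverts the implied
  season-to-season correlation when a specific value is wanted), with an
  equicorrelation of 0.6 between index innovations, matching the strong
  co-variation of regional ocean indices. SST-named series are emitted as
  `offset + scale × (−latent)` (defaults 11.5 °C, 1 °C per unit) so the
  warm phase is the low-nutrient phase.
* **Kelp link** — E_y = max(0, α + β·x_y + ε). Defaults are the
  published-scale strongest models: north α = 3.04 km², β = −0.77 km² per
  winter MOCI unit, and noise σ derived from a target R² of 0.87 via
  σ = |β|·sd(x)·√((1−R²)/R²); south α = 5.52, β = −0.19, target R² 0.57.
  The truncation at 0 is a deliberate physicality constraint; at the
  default parameters P(α + βx + ε < 0) ≈ 10⁻⁵, so it does not bias the
  calibration studies.
* **Rasterisation** — the regional extent is split across 10 bands per
  region by a fixed unimodal (Gaussian-profile) weight vector — kelp beds
  are patchy, and a non-uniform profile makes band-level QC actually
  selective — then equally across a band's pixels, capped at the physical
  900 m² per pixel. Cloud dropout blanks a fixed fraction (default 0.3) of
  a band-year's pixels with probability 0.08 per band-year, which yields
  roughly 4–7 missing region-years out of 30 after QC, the density of gaps
  seen in real summer canopy records.
* **Collapse scenario** — from the split year on, observed pixel areas are
  multiplied by a suppression factor while the indices are untouched. This
  is the minimal model of a biotic ceiling (urchin grazing) decoupling
  canopy from climate.

What the generator does **not** emulate: spatial autocorrelation of clouds,
within-band kelp texture, index non-stationarity and trends, observation
error in the canopy product, and any biotic dynamics beyond the scalar
suppression. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the stated statistical conditions, not
the ecological fidelity of any particular fit to real data.

## Problem sizes and numerical choices

The replicated studies in `kelpcast.experiments` run the statistical stages
at the published scale (23 pre-split years, β = −0.77, target R² 0.87, 500
replicates for recovery and screen calibration). Studies that exercise the
pixel rasteriser use extents scaled down 50× with ~20–40 pixels per band
(200 replicates for the decoupling study): the QC and aggregation
arithmetic is scale-free, each 0.1° band must hold its share of extent
within the 900 m² pixel cap, and at full scale that means hundreds of
pixels per band — cost without statistical content. The exactness of the
rasterise → aggregate round trip is asserted separately to 10⁻⁹ km².

The screen's type-I calibration uses independent white-noise indices
(φ = 0, no cross-correlation): each of the 16 cells per replicate is then
an independent test and the rejection count has an exact binomial
reference. With the default persistent, cross-correlated ocean the
*expected* rate is unchanged but cells are positively dependent, which only
inflates the variance of the measured rate.

Determinism: every generator output is a pure function of (config, seed);
replicate seeds derive from a base seed as (base·1,000,003 + rep) mod 2³¹.
CSV outputs are written with a fixed float format, so identical inputs give
byte-identical report bundles.

## Known limitations

* Annual series are short and autocorrelated; plain OLS p-values are
  anti-conservative if residuals are persistent.
* The screen's per-cell α with ~64 cells implies ~3 false positives per
  full screen; AIC selection among significant cells does not correct this.
* Excluding flagged bands without rescaling biases accepted region-years
  slightly low, most in years with one flagged central (high-weight) band.
* The leave-one-out "precision" is an in-sample statistic; genuinely
  predictive skill is what the percent errors measure.
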
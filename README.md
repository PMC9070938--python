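# kelpcast

Seasonal environmental prediction of summer bull kelp (*Nereocystis
luetkeana*) canopy extent in northern California, as a tested, reusable
Python pipeline.

Bull kelp is an annual species: the microscopic gametophyte overwinters,
and the visible surface canopy peaks the following summer. Winter ocean
conditions — temperature and upwelling-driven nutrient supply, synthesized
by indices such as the Multivariate Ocean Climate Indicator (MOCI), buoy
sea-surface temperature (SST), and the Biologically Effective Upwelling
Transport Index (BEUTI) — therefore carry predictive information about the
summer canopy. `kelpcast` implements the full analysis chain from raw
satellite pixels to out-of-period forecasts:

1. **Canopy QC / aggregation** — quarterly 30 × 30 m Landsat-style pixel
   records (canopy area 0–900 m², missing when cloud-obscured) are summed
   into 0.1° latitude bands; a band-year with fewer than 90% of the band's
   median pixel count is flagged missing, and a region-year (north/south of
   Point Arena, 39°N) with more than 10% flagged bands is itself missing.
   The result is an annual summer canopy extent series *E_y* (km²) per
   region.
2. **Seasonal predictors** — monthly index series are averaged over
   fall (OND, lagged one year), winter (JFM), spring (AMJ) and summer (JAS)
   and aligned to the kelp year.
3. **Regression screen and AIC selection** — for each region and each
   (index, season), the univariate model *E_y = α + β·x_y + ε_y* is fitted
   by OLS; cells with slope p ≥ 0.05 are masked, and the best significant
   model per region minimises the Gaussian AIC
   *n·ln(2πSSE/n) + n + 2k*, *k* = 2.
4. **Leave-one-out validation** — precision = mean refit R² over
   leave-one-year-out refits; predictability error =
   |measured − predicted| / measured × 100 per held-out year.
5. **Forecasting** — the model trained on the pre-collapse years
   (1991–2013 by default) predicts 2014 onward; exploding forecast errors
   against observed canopy are the signature of a biotic regime shift
   (urchin herbivory) that the ocean indices cannot see.
6. **Synthetic data** — an AR(1)/linear-link generator reproduces the whole
   study layout with known ground truth (indices, pixel grids, cloud
   dropout, post-split suppression), so every stage is testable end to end.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_validate_and_forecast.py` simulates the default
scenario, suppresses observed canopy to 10% after 2014, and prints:

```
pre-collapse model (21 years): north_kelp = 0.06 - 0.01 * winter MOCI_south, R² = 0.61
LOO precision (mean refit R²): 0.61
LOO predictability error: 10% (sd 8%)

forecast vs suppressed observations:
 year  predicted_km2  observed_km2  error_pct
 2014          0.061         0.006    936.042
 ...
mean post-split error: 921%
```

The pre-collapse model predicts held-out years to ~10%; after the
simulated collapse the same model misses by ~900% because the observed
canopy is no longer set by the environment. That contrast — small
cross-validated errors before the split, order-of-magnitude errors after —
is the analysis' central diagnostic.

The same stages are available from the shell:

```bash
kelpcast simulate --seed 42 --out-dir data/
kelpcast run-all --config pipeline.yaml
```

with subcommands `aggregate`, `seasons`, `screen`, `fit`, `validate` and
`forecast` for the individual stages (CSV in, CSV out).

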
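"""Simulate a kelp–ocean scenario with known ground truth.

Builds the default two-region scenario: AR(1) monthly ocean indices, a
negative winter-index → summer-canopy link per region, pixel rasterisation
over 0.1° latitude bands, and cloud dropout.  Prints the latent truth and
how much of the pixel record the clouds removed.
"""

import numpy as np

from kelpcast.experiments import scaled_scenario
from kelpcast import gen_canopy_pixels, gen_monthly_indices

cfg = scaled_scenario(seed=42)
indices = gen_monthly_indices(cfg)
pixels, truth = gen_canopy_pixels(cfg, indices)

north = truth.regional.query("region == 'north'").head(5)
print("first north truth years (extent = max(0, alpha + beta*winter_index + noise)):")
print(north[["year", "x", "epsilon", "extent_km2"]].to_string(index=False))

n_missing = int(pixels["canopy_area_m2"].isna().sum())
print(f"\npixel records: {len(pixels)}  cloud-blanked: {n_missing} "
      f"({100 * n_missing / len(pixels):.1f}%)")
print(f"band-years hit by cloud events: {len(truth.dropout)}")
print("\nEach truth row is one region-year: x is the winter driver index, and")
print("extent_km2 is the regional summer canopy the pixel grid was built from.")
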
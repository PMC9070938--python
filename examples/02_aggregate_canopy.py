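"""Quality-control and aggregate pixel records into regional annual extents.

Cloudy pixels cannot be told apart from kelp-free water, so band-years with
too few observed pixels are flagged (< 90% of the band's median count), and
a region-year with > 10% flagged bands is declared missing rather than
biased low.
"""

from kelpcast.experiments import scaled_scenario
from kelpcast import aggregate_canopy, gen_canopy_pixels, gen_monthly_indices

cfg = scaled_scenario(seed=42)
indices = gen_monthly_indices(cfg)
pixels, truth = gen_canopy_pixels(cfg, indices)

regional = aggregate_canopy(pixels)
north = regional.query("region == 'north'")
print("north region, first 8 years:")
print(north.head(8).to_string(index=False))

missing = regional["extent_km2"].isna().groupby(regional["region"]).sum()
print(f"\nmissing region-years after QC: north={int(missing['north'])}, "
      f"south={int(missing['south'])} of 30 each")
print("\nextent_km2 is the summed canopy of unflagged bands; a blank extent")
print("means too many bands failed QC that summer to trust the total.")
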
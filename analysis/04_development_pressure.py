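#!/usr/bin/env python
"""Classify sector suitability into development-pressure categories.

Each of the fourteen 0-1 sector surfaces is z-scored per country and
binned into six percentile categories; the combined map keeps the highest
category per cell, and cells reaching high/very high (5-6) form the
high-pressure mask.  Writes rasters and per-country bin counts under
results/pressure/.
"""

import numpy as np

from _study import outdir, study_landscape
from landprior import classify_dpi, combine_pressure, write_layer
from landprior.development_pressure import bin_counts_frame

def main():
    out = outdir("pressure")
    land = study_landscape()
    categories = [classify_dpi(d, land.countries) for d in land.dpi]
    pressure = combine_pressure(categories)

    write_layer(pressure.combined, out / "pressure_combined.asc")
    write_layer(pressure.high_mask, out / "pressure_high.asc")
    bin_counts_frame(pressure, land.countries).to_csv(
        out / "bin_counts.csv", index=False)

    valid = pressure.combined.valid
    high_pct = 100 * pressure.high_mask.values[valid].mean()
    dist = np.bincount(pressure.combined.values[valid].astype(int),
                       minlength=7)[1:]
    print(f"{len(categories)} sectors classified; combined category "
          f"distribution (1..6): {dist.tolist()}; high/very-high pressure "
          f"covers {high_pct:.1f}% of valid land -> {out}")

if __name__ == "__main__":
    main()
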
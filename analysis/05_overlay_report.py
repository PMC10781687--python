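#!/usr/bin/env python
"""Overlay the prioritized areas with protection and development pressure.

Prioritized areas are the 90%-NCP + all-species solution.  Reports the
share of prioritized land that is protected, the share under high
development pressure (both against the prioritized-area and total-land
denominators), sector attribution with a "multiple sectors" class, and
per-country/per-biome overlap.  Writes results/overlay/.
"""

import numpy as np

from _study import SOLVE_OPTIONS, outdir, study_landscape
from landprior import (Layer, overlap_stats, prepare_protected_areas,
                       run_target_sweep, write_layer)
from landprior.overlay_report import strata_from_categorical

def main():
    out = outdir("overlay")
    land = study_landscape()
    pa_mask, _ = prepare_protected_areas(land.pa_records, land.grid)
    sweep = run_target_sweep(land, [0.9], include_species=True,
                             options=SOLVE_OPTIONS)
    priority = sweep.solution_at(0.9).selection_layer(land.grid, "priority")

    from landprior import classify_dpi, combine_pressure
    categories = [classify_dpi(d, land.countries) for d in land.dpi]
    pressure = combine_pressure(categories)
    per_sector_high = {
        name: Layer(land.grid, (lyr.values >= 5).astype(np.uint8)
                    * lyr.valid, name=name)
        for name, lyr in pressure.sectors.items()}

    strata = {}
    strata.update(strata_from_categorical(land.countries, "country_"))
    strata.update(strata_from_categorical(land.biomes, "biome_"))

    report = overlap_stats(priority, pa_mask, pressure.high_mask,
                           strata=strata, per_sector_high=per_sector_high)
    report.to_json(out / "overlap_report.json")
    report.stratum_frame().to_csv(out / "per_stratum.csv", index=False)
    write_layer(priority, out / "priority.asc")

    print(f"prioritized area: {report.fractions['prioritized_of_land']:.1%} "
          f"of land; {report.pct_prioritized_protected:.1f}% of it protected;"
          f" {report.pct_prioritized_high_pressure:.1f}% under high "
          f"development pressure ({report.pct_land_area_overlap:.1f}% of all "
          f"land); multiple-sector share {report.multiple_sector_pct:.1f}% "
          f"-> {out}")

if __name__ == "__main__":
    main()
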
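#!/usr/bin/env python
"""Generate the synthetic study landscape and write its layers.

Writes the landcover, elevation, country/biome strata, an example NCP
surface and the protected-area register under results/landscape/.
"""

import pandas as pd

from _study import SEED, STUDY_PARAMS, outdir, study_landscape
from landprior import write_layer

def main():
    out = outdir("landscape")
    land = study_landscape()

    for lyr in (land.landcover, land.elevation, land.countries,
                land.biomes, land.population_proxy, land.ncp[0]):
        write_layer(lyr, out / f"{lyr.name}.asc")

    pd.DataFrame(
        [(r.id, r.geometry_kind, r.status, r.designation,
          round(r.reported_area_km2, 1)) for r in land.pa_records],
        columns=["id", "geometry_kind", "status", "designation",
                 "reported_area_km2"],
    ).to_csv(out / "pa_records.csv", index=False)

    pd.DataFrame(
        [(s.species_id, s.taxon, s.seasonal_code,
          ";".join(map(str, sorted(s.habitat_codes))),
          round(s.elevation_min_m), round(s.elevation_max_m),
          int(s.range_mask.values.sum()))
         for s in land.species],
        columns=["species_id", "taxon", "seasonal_code", "habitat_codes",
                 "elev_min_m", "elev_max_m", "range_cells"],
    ).to_csv(out / "species_traits.csv", index=False)

    natural_pct = 100 * land.natural_mask().mean()
    print(f"landscape seed {SEED}: {STUDY_PARAMS.grid.n_rows}x"
          f"{STUDY_PARAMS.grid.n_cols} cells, {natural_pct:.1f}% natural or "
          f"semi-natural, {len(land.species)} species records "
          f"({sum(s.seasonal_code > 1 for s in land.species)} seasonal), "
          f"{len(land.pa_records)} PA records -> {out}")

if __name__ == "__main__":
    main()
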
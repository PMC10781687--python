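"""Area of Habitat (AOH): refine species range masks by habitat class and
elevational limits, with majority-rule aggregation between resolutions.

An AOH keeps only the part of a species' range whose landcover class
matches the species' habitat associations and whose elevation lies inside
the species' accepted band.  Elevational limits are inclusive at both
bounds.  Seasonal bird records produce separate AOH objects keyed
``(species_id, seasonal_code)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core_model import GridSpec, Layer
from .synthetic_landscape import SpeciesTrait


@dataclass
class AOH:
    """A species' area of habitat on the planning grid."""

    species_id: str
    seasonal_code: int
    mask: Layer  # boolean
    area_km2: float
    empty: bool = False

    @property
    def feature_id(self) -> str:
        """Feature key: seasonal bird distributions are separate features."""
        if self.seasonal_code == 1:
            return self.species_id
        return f"{self.species_id}_s{self.seasonal_code}"


def aggregate_majority(fine: Layer, factor: int) -> Layer:
    """Aggregate a categorical layer by the modal class of each
    ``factor x factor`` block.

    Nodata cells are excluded from the vote; an all-nodata block maps to
    nodata.  Ties break to the lowest class code.  Grid dimensions must be
    divisible by ``factor`` (no partial blocks).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fine.copy()
    g = fine.grid
    if g.n_rows % factor or g.n_cols % factor:
        raise ValueError(
            f"grid {g.shape} not divisible by aggregation factor {factor}")
    nr, nc = g.n_rows // factor, g.n_cols // factor
    coarse_grid = GridSpec(nr, nc, g.cell_side_km * factor)

    vals = fine.values.reshape(nr, factor, nc, factor).swapaxes(1, 2)
    valid = fine.valid.reshape(nr, factor, nc, factor).swapaxes(1, 2)
    out = np.zeros((nr, nc), dtype=fine.values.dtype)
    out_nodata = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            block = vals[r, c][valid[r, c]]
            if block.size == 0:
                out_nodata[r, c] = True
                continue
            classes, counts = np.unique(block, return_counts=True)
            # np.unique sorts classes ascending, so argmax of counts picks
            # the lowest class code among tied maxima
            out[r, c] = classes[np.argmax(counts)]
    return Layer(coarse_grid, out, nodata=out_nodata,
                 name=f"{fine.name}_agg{factor}" if fine.name else "")


def build_aoh(trait: SpeciesTrait, landcover: Layer,
              elevation: Layer) -> AOH:
    """Refine a range mask to its area of habitat.

    ``mask = range AND landcover in habitat_codes AND
    elevation_min <= elevation <= elevation_max`` (bounds inclusive).
    An empty AOH is allowed but flagged.
    """
    grid = trait.range_mask.grid
    if landcover.grid != grid or elevation.grid != grid:
        raise ValueError("landcover/elevation grid does not match range mask")
    rng_mask = trait.range_mask.values.astype(bool) & trait.range_mask.valid
    habitat_ok = np.isin(landcover.values, sorted(trait.habitat_codes))
    habitat_ok &= landcover.valid
    elev_ok = ((elevation.values >= trait.elevation_min_m)
               & (elevation.values <= trait.elevation_max_m)
               & elevation.valid)
    mask = rng_mask & habitat_ok & elev_ok
    area = float(mask.sum()) * grid.cell_area_km2
    layer = Layer(grid, mask.astype(np.uint8),
                  name=f"aoh_{trait.species_id}_s{trait.seasonal_code}")
    return AOH(trait.species_id, trait.seasonal_code, layer, area,
               empty=not mask.any())


def aoh_area_km2(aoh: AOH) -> float:
    """Habitat area: count of mask cells times the cell area."""
    return float(aoh.mask.values.astype(bool).sum()) * aoh.mask.grid.cell_area_km2


def build_aoh_set(traits: Iterable[SpeciesTrait], landcover: Layer,
                  elevation: Layer) -> list[AOH]:
    """AOH for every species record (seasonal records stay separate)."""
    return [build_aoh(t, landcover, elevation) for t in traits]


def aoh_summary(aohs: Iterable[AOH]) -> pd.DataFrame:
    """CSV-ready summary: species_id, seasonal_code, area_km2, empty."""
    return pd.DataFrame(
        [(a.species_id, a.seasonal_code, a.area_km2, a.empty) for a in aohs],
        columns=["species_id", "seasonal_code", "area_km2", "empty"])
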
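"""Development-pressure classification.

Each sector's 0–1 suitability surface is z-scored per country and binned
into six categories at the empirical 10/25/50/75/90th percentiles:
very low (<=10th), low (>10th–25th), medium-low (>25th–50th), medium-high
(>50th–75th), high (>75th–90th), very high (>90th).  The combined pressure
map retains the highest category across sectors, and the high-pressure
mask keeps categories 5 and 6.

Percentiles are empirical nearest-rank statistics on the sorted z-scores:
deterministic, and ties resolve per the closed-left band endpoints (a tied
value can only fall in the lower category).  Since z-scoring is a monotone
per-country transform, classification is invariant to positive affine
rescaling of a country's values; the z-scores are retained for
cross-sector comparability.  An urban pressure surface is just another
0–1 layer fed through the same path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import Layer

_PERCENTILES = (10.0, 25.0, 50.0, 75.0, 90.0)
HIGH_CATEGORIES = (5, 6)


@dataclass
class PressureMap:
    sectors: dict[str, Layer]  # per-sector categories in {1..6}
    combined: Layer            # cellwise max category
    high_mask: Layer           # combined in {5, 6}

    @property
    def sector_names(self) -> list[str]:
        return list(self.sectors)


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    n = sorted_vals.size
    k = int(np.ceil(pct / 100.0 * n)) - 1
    return float(sorted_vals[max(0, min(k, n - 1))])


def classify_dpi(dpi: Layer, countries: Layer,
                 global_bins: bool = False) -> Layer:
    """Six-category per-country percentile classification of a 0–1
    suitability layer.

    ``global_bins`` pools the percentile cut-points across countries
    (z-scores stay per-country); the default computes them per country.
    Countries with fewer than two valid cells, or zero variance, collapse
    to category 1 (every value ties at or below every cut-point).
    """
    if countries.grid != dpi.grid:
        raise ValueError("countries layer grid does not match dpi grid")
    valid = dpi.valid & countries.valid
    vals = np.asarray(dpi.values, dtype=float)
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise ValueError("dpi values must lie in [0, 1] on valid cells")

    z = np.full(dpi.grid.shape, np.nan)
    for code in np.unique(countries.values[valid]):
        sel = valid & (countries.values == code)
        n = int(sel.sum())
        if n < 2:
            warnings.warn(f"country {code}: fewer than 2 valid cells, "
                          "assigned category 1 (very low)")
            z[sel] = -np.inf  # forces category 1
            continue
        v = vals[sel]
        sd = v.std()
        if sd == 0:
            z[sel] = 0.0  # all tie: <= every percentile, category 1
        else:
            z[sel] = (v - v.mean()) / sd

    cat = np.zeros(dpi.grid.shape, dtype=np.uint8)
    if global_bins:
        pooled = np.sort(z[valid & np.isfinite(z)])
        cuts_global = [_nearest_rank(pooled, p) for p in _PERCENTILES] \
            if pooled.size else [0.0] * 5
    for code in np.unique(countries.values[valid]):
        sel = valid & (countries.values == code)
        zc = z[sel]
        finite = np.isfinite(zc)
        if global_bins:
            cuts = cuts_global
        else:
            zs = np.sort(zc[finite])
            cuts = ([_nearest_rank(zs, p) for p in _PERCENTILES]
                    if zs.size else [0.0] * 5)
        c = np.ones(zc.shape, dtype=np.uint8)
        for cut in cuts:
            c += (zc > cut).astype(np.uint8)
        c[~finite] = 1
        cat[sel] = c
    return Layer(dpi.grid, cat, nodata=~valid,
                 name=f"{dpi.name}_category" if dpi.name else "dpi_category")


def combine_pressure(per_sector: Sequence[Layer]) -> PressureMap:
    """Retain the highest category across sector layers; the high-pressure
    mask keeps categories 5–6.  Cells nodata in every sector stay nodata."""
    if not per_sector:
        raise ValueError("need at least one sector layer")
    grid = per_sector[0].grid
    for lyr in per_sector:
        if lyr.grid != grid:
            raise ValueError("sector layers disagree on grid")
    stack = np.stack([np.where(lyr.nodata, 0, lyr.values)
                      for lyr in per_sector]).astype(np.int16)
    combined_vals = stack.max(axis=0)
    all_nodata = np.all([lyr.nodata for lyr in per_sector], axis=0)
    combined = Layer(grid, combined_vals.astype(np.uint8),
                     nodata=all_nodata, name="pressure_combined")
    high = (combined_vals >= HIGH_CATEGORIES[0]) & ~all_nodata
    high_mask = Layer(grid, high.astype(np.uint8), name="pressure_high")
    return PressureMap(
        sectors={lyr.name or f"sector_{k}": lyr
                 for k, lyr in enumerate(per_sector)},
        combined=combined, high_mask=high_mask)


def bin_counts_frame(pressure: PressureMap, countries: Layer) -> pd.DataFrame:
    """Per-country category counts per sector (CSV-ready)."""
    rows = []
    for name, lyr in pressure.sectors.items():
        for code in np.unique(countries.values):
            sel = (countries.values == code) & lyr.valid
            for cat in range(1, 7):
                rows.append((name, int(code), cat,
                             int(((lyr.values == cat) & sel).sum())))
    return pd.DataFrame(rows, columns=["sector", "country", "category",
                                       "n_cells"])
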
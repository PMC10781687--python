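"""Overlay statistics: protection coverage of prioritized areas,
development-pressure overlap, and sector/stratum attribution.

All area arithmetic is cell counting times the cell area (equal-area
grids); no geodesic computation.  Percentages are presented to one
decimal; the machine-readable report keeps raw fractions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import Layer

MULTIPLE_SECTORS = "multiple sectors"


def _as_bool(layer: Layer) -> np.ndarray:
    return layer.values.astype(bool) & layer.valid


@dataclass
class OverlapReport:
    pct_prioritized_protected: float
    pct_prioritized_high_pressure: float
    pct_land_area_overlap: float
    per_sector: dict[str, tuple[float, float]]  # (pct of prioritized, pct of land)
    per_stratum: dict[str, float]
    multiple_sector_pct: float
    fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "pct_prioritized_protected": round(self.pct_prioritized_protected, 1),
            "pct_prioritized_high_pressure":
                round(self.pct_prioritized_high_pressure, 1),
            "pct_land_area_overlap": round(self.pct_land_area_overlap, 1),
            "multiple_sector_pct": round(self.multiple_sector_pct, 1),
            "per_sector": {k: [round(a, 1), round(b, 1)]
                           for k, (a, b) in sorted(self.per_sector.items())},
            "per_stratum": {k: round(v, 1)
                            for k, v in sorted(self.per_stratum.items())},
            "fractions": {k: self.fractions[k] for k in sorted(self.fractions)},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def stratum_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.per_stratum.items()),
                            columns=["stratum", "pct_high_pressure_overlap"])


def strata_from_categorical(layer: Layer, prefix: str = "") -> dict[str, Layer]:
    """Expand a categorical layer (countries, biomes) into boolean
    stratum masks keyed ``prefix<code>``."""
    out: dict[str, Layer] = {}
    for code in np.unique(layer.values[layer.valid]):
        mask = (layer.values == code) & layer.valid
        out[f"{prefix}{code}"] = Layer(layer.grid, mask.astype(np.uint8),
                                       name=f"{prefix}{code}")
    return out


def overlap_stats(
    priority_mask: Layer,
    pa_mask: Layer,
    high_pressure: Layer,
    strata: Mapping[str, Layer] | None = None,
    per_sector_high: Mapping[str, Layer] | None = None,
) -> OverlapReport:
    """Cell-count overlay of prioritized areas against protection and
    development pressure.

    Two denominators are reported, as in gap analyses: the prioritized
    area itself, and total land area (the grid's valid cells).  Per-
    stratum overlap is ``|priority AND high AND stratum| / |stratum|``.
    """
    grid = priority_mask.grid
    for lyr in (pa_mask, high_pressure):
        if lyr.grid != grid:
            raise ValueError("overlay layers disagree on grid")
    prio = _as_bool(priority_mask)
    if not prio.any():
        raise ValueError("priority mask is empty")
    pa = _as_bool(pa_mask)
    high = _as_bool(high_pressure)
    land = priority_mask.valid
    n_land = int(land.sum())
    n_prio = int(prio.sum())
    overlap = prio & high
    n_overlap = int(overlap.sum())

    per_sector: dict[str, tuple[float, float]] = {}
    multiple_pct = 0.0
    if per_sector_high:
        attribution, labels = sector_attribution(priority_mask,
                                                 per_sector_high)
        for code, label in labels.items():
            n = int((attribution.values == code).sum())
            per_sector[label] = (100.0 * n / n_prio, 100.0 * n / n_land)
        if MULTIPLE_SECTORS in per_sector:
            multiple_pct = per_sector[MULTIPLE_SECTORS][0]

    per_stratum: dict[str, float] = {}
    if strata:
        for name, lyr in strata.items():
            if lyr.grid != grid:
                raise ValueError(f"stratum {name!r} grid mismatch")
            s = _as_bool(lyr)
            n_s = int(s.sum())
            if n_s == 0:
                warnings.warn(f"stratum {name!r} has zero area, omitted")
                continue
            per_stratum[name] = 100.0 * int((overlap & s).sum()) / n_s

    return OverlapReport(
        pct_prioritized_protected=100.0 * int((prio & pa).sum()) / n_prio,
        pct_prioritized_high_pressure=100.0 * n_overlap / n_prio,
        pct_land_area_overlap=100.0 * n_overlap / n_land,
        per_sector=per_sector,
        per_stratum=per_stratum,
        multiple_sector_pct=multiple_pct,
        fractions={
            "prioritized_of_land": n_prio / n_land,
            "protected_of_prioritized": int((prio & pa).sum()) / n_prio,
            "high_pressure_of_prioritized": n_overlap / n_prio,
            "overlap_of_land": n_overlap / n_land,
        })


def sector_attribution(
    priority_mask: Layer,
    per_sector_high: Mapping[str, Layer],
) -> tuple[Layer, dict[int, str]]:
    """Label each prioritized high-pressure cell with its unique high
    sector, or "multiple sectors" where two or more sectors are high.

    Returns the categorical layer (0 = unlabeled) and the code→label map;
    the labeled classes partition the overlap mask.
    """
    if not per_sector_high:
        raise ValueError("need at least one sector mask")
    grid = priority_mask.grid
    prio = _as_bool(priority_mask)
    names = sorted(per_sector_high)
    stack = []
    for name in names:
        lyr = per_sector_high[name]
        if lyr.grid != grid:
            raise ValueError(f"sector {name!r} grid mismatch")
        stack.append(_as_bool(lyr))
    high_count = np.sum(stack, axis=0)
    codes = np.zeros(grid.shape, dtype=np.int16)
    labels: dict[int, str] = {}
    for k, name in enumerate(names, start=1):
        codes[prio & stack[k - 1] & (high_count == 1)] = k
        labels[k] = name
    multi_code = len(names) + 1
    codes[prio & (high_count >= 2)] = multi_code
    labels[multi_code] = MULTIPLE_SECTORS
    return Layer(grid, codes, name="sector_attribution"), labels
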
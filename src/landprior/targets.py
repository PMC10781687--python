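"""Representation targets: the species target rule and proportional NCP
targets.

The species rule assigns each species a protected fraction of its area of
habitat A (km²):

* f(A) = 1        for A <= 1,000 km² (full protection of tiny ranges),
* f(A) = 0.10     for A >= 250,000 km²,
* log-linear in between:
  f(A) = 1 - 0.9 * (log A - log 1000) / (log 250000 - log 1000)
  (the ratio is base-invariant),

and the resulting target area min(f(A)·A, cap) is capped at 1,000,000 km²,
which binds only for A > 10,000,000 km² under the defaults.  A exactly at
the lower knot uses the interpolant (which equals 1.0 there); A exactly at
the upper knot uses 0.10 — continuity makes the choice immaterial, stating
it removes ambiguity.

NCP targets are a fixed fraction of each layer's total value; species
targets are identical across NCP levels, and migratory seasonal bird
distributions are targeted independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import FeatureTable


@dataclass(frozen=True)
class TargetRuleParams:
    """Knots of the species target rule (all areas in km²)."""

    full_protection_below_km2: float = 1_000.0
    fraction_floor: float = 0.10
    floor_above_km2: float = 250_000.0
    cap_km2: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not self.full_protection_below_km2 < self.floor_above_km2:
            raise ValueError("lower knot must lie below the upper knot")
        if not 0.0 < self.fraction_floor <= 1.0:
            raise ValueError("fraction_floor must lie in (0, 1]")
        if self.cap_km2 <= 0:
            raise ValueError("cap must be positive")


def species_target_fraction(aoh_area_km2: float,
                            params: TargetRuleParams = TargetRuleParams()
                            ) -> float:
    """The protected fraction f(A); continuous, non-increasing in A."""
    if aoh_area_km2 < 0:
        raise ValueError("AOH area must be nonnegative")
    a_lo = params.full_protection_below_km2
    a_hi = params.floor_above_km2
    if aoh_area_km2 <= a_lo:
        return 1.0
    if aoh_area_km2 >= a_hi:
        return params.fraction_floor
    t = (np.log(aoh_area_km2) - np.log(a_lo)) / (np.log(a_hi) - np.log(a_lo))
    return float(1.0 - (1.0 - params.fraction_floor) * t)


def species_target_area(aoh_area_km2: float,
                        params: TargetRuleParams = TargetRuleParams()
                        ) -> float:
    """Target area in km²: ``min(f(A) * A, cap)``."""
    f = species_target_fraction(aoh_area_km2, params)
    return float(min(f * aoh_area_km2, params.cap_km2))


def target_rule_branch(aoh_area_km2: float,
                       params: TargetRuleParams = TargetRuleParams()) -> str:
    """Which branch of the rule applied: full | interp | floor | capped."""
    if species_target_fraction(aoh_area_km2, params) * aoh_area_km2 \
            > params.cap_km2:
        return "capped"
    if aoh_area_km2 <= params.full_protection_below_km2:
        return "full"
    if aoh_area_km2 >= params.floor_above_km2:
        return "floor"
    return "interp"


def build_target_vector(features: FeatureTable,
                        species_areas: Mapping[str, float],
                        ncp_level: float,
                        include_species: bool = True,
                        params: TargetRuleParams = TargetRuleParams()
                        ) -> dict[str, float]:
    """Per-feature targets T_j.

    NCP features get ``ncp_level`` times their total available amount;
    species features get the species rule applied to their AOH area (keyed
    by feature id, so seasonal bird distributions are independent), or 0
    when ``include_species`` is false.
    """
    if not 0.0 <= ncp_level <= 1.0:
        raise ValueError("ncp_level must lie in [0, 1]")
    targets: dict[str, float] = {}
    for fid in features.feature_ids:
        if features.kind[fid] == "ncp":
            targets[fid] = ncp_level * features.total_available(fid)
        else:
            if include_species:
                targets[fid] = species_target_area(species_areas[fid], params)
            else:
                targets[fid] = 0.0
    return targets


def targets_to_frame(targets: Mapping[str, float],
                     features: FeatureTable,
                     species_areas: Mapping[str, float] | None = None,
                     params: TargetRuleParams = TargetRuleParams()
                     ) -> pd.DataFrame:
    """CSV-ready target table with the rule branch for species features."""
    rows = []
    for fid, t in targets.items():
        if features.kind[fid] == "species" and species_areas is not None:
            branch = target_rule_branch(species_areas[fid], params)
        else:
            branch = ""
        rows.append((fid, t, branch))
    return pd.DataFrame(rows, columns=["feature_id", "target_km2",
                                       "rule_branch"])
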
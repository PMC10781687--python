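"""Shared data model: equal-area grids, layers, planning units, features,
minimum-set problem instances and solutions.

Conventions
-----------
Planning-unit ids are 0-based and row-major over the grid
(``unit_id = row * n_cols + col``); every cross-module reference uses this
convention.  Cost is per-cell land area in km² (equal across cells on the
synthetic equal-area grids), mirroring a minimum-area objective; an
alternative cost layer may be supplied but area is the default.  Feature
amounts ``r_ij`` are stored sparsely — zero amounts are omitted, since
species × unit matrices are overwhelmingly sparse.  Cells flagged nodata in
any required input layer are unavailable and never enter a problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GridSpec:
    """An abstract equal-area raster lattice.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the grid has ``n_rows * n_cols`` cells.
    cell_side_km
        Side length of each (square) cell in km.  The cell area is the
        square of this, so grids are equal-area by construction.
    """

    n_rows: int
    n_cols: int
    cell_side_km: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_side_km <= 0:
            raise ValueError("cell_side_km must be positive")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side_km ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def unit_ids(self) -> np.ndarray:
        """All unit ids, row-major."""
        return np.arange(self.n_cells, dtype=np.int64)


@dataclass
class Layer:
    """A single-band raster on a :class:`GridSpec`.

    ``values`` is a ``(n_rows, n_cols)`` array (real or categorical);
    ``nodata`` is a boolean mask of the same shape; nodata cells carry no
    value semantics.  ``name`` identifies the layer when it acts as a
    feature.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape} != grid {self.grid.shape}"
            )
        if self.nodata is None:
            self.nodata = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.grid.shape:
                raise ValueError("nodata mask shape does not match grid")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata

    def flat(self) -> np.ndarray:
        """Row-major flattened values (unit-id order)."""
        return self.values.reshape(-1)

    def copy(self) -> "Layer":
        return Layer(self.grid, self.values.copy(), self.nodata.copy(), self.name)


def _check_same_grid(layers: Iterable[Layer], grid: GridSpec) -> None:
    for lyr in layers:
        if lyr.grid != grid:
            raise ValueError(f"layer {lyr.name!r} is not on the expected grid")


@dataclass
class PlanningUnits:
    """The selectable cells of a grid with their costs (km² of land)."""

    grid: GridSpec
    available: np.ndarray
    cost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.available = np.asarray(self.available, dtype=bool)
        if self.available.shape != self.grid.shape:
            raise ValueError("available mask shape does not match grid")
        if self.cost is None:
            self.cost = np.full(self.grid.shape, self.grid.cell_area_km2)
        else:
            self.cost = np.asarray(self.cost, dtype=float)
            if self.cost.shape != self.grid.shape:
                raise ValueError("cost shape does not match grid")
        if np.any(self.cost[self.available] <= 0):
            raise ValueError("cost must be positive on available cells")

    @property
    def ids(self) -> np.ndarray:
        """Ids of available units, ascending."""
        return np.flatnonzero(self.available.reshape(-1))

    @property
    def n_available(self) -> int:
        return int(self.available.sum())

    def cost_of(self, unit_ids: Iterable[int]) -> float:
        flat = self.cost.reshape(-1)
        return float(sum(flat[i] for i in unit_ids))

    @property
    def total_area_km2(self) -> float:
        return float(self.cost.reshape(-1)[self.ids].sum())


class FeatureTable:
    """Sparse per-feature amounts r_ij over planning units.

    Amounts are stored as ``{feature_id: {unit_id: amount}}`` with zero
    entries omitted.  ``kind`` is ``"ncp"`` or ``"species"`` per feature.
    """

    def __init__(self) -> None:
        self._amounts: dict[str, dict[int, float]] = {}
        self.kind: dict[str, str] = {}

    def add_feature(self, feature_id: str, kind: str,
                    unit_ids: np.ndarray, amounts: np.ndarray) -> None:
        if feature_id in self._amounts:
            raise ValueError(f"duplicate feature {feature_id!r}")
        if kind not in ("ncp", "species"):
            raise ValueError(f"unknown feature kind {kind!r}")
        amounts = np.asarray(amounts, dtype=float)
        if np.any(amounts < 0):
            raise ValueError(f"negative amount for feature {feature_id!r}")
        nz = amounts > 0
        self._amounts[feature_id] = {
            int(u): float(a) for u, a in zip(np.asarray(unit_ids)[nz], amounts[nz])
        }
        self.kind[feature_id] = kind

    @property
    def feature_ids(self) -> list[str]:
        return list(self._amounts)

    def __len__(self) -> int:
        return len(self._amounts)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._amounts

    def amounts(self, feature_id: str) -> dict[int, float]:
        return self._amounts[feature_id]

    def total_available(self, feature_id: str,
                        exclude: frozenset[int] | set[int] = frozenset()) -> float:
        amt = self._amounts[feature_id]
        if not exclude:
            return float(sum(amt.values()))
        return float(sum(a for u, a in amt.items() if u not in exclude))

    def totals(self) -> dict[str, float]:
        return {f: self.total_available(f) for f in self._amounts}

    def attainment(self, feature_id: str, selected: Iterable[int]) -> float:
        amt = self._amounts[feature_id]
        return float(sum(amt.get(u, 0.0) for u in selected))

    # -- CSV round-trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f, u, a)
            for f, amt in self._amounts.items()
            for u, a in sorted(amt.items())
        ]
        return pd.DataFrame(rows, columns=["feature_id", "unit_id", "amount"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   kind: Mapping[str, str]) -> "FeatureTable":
        ft = cls()
        for fid, grp in df.groupby("feature_id", sort=False):
            ft.add_feature(str(fid), kind[str(fid)],
                           grp["unit_id"].to_numpy(),
                           grp["amount"].to_numpy())
        return ft

    @classmethod
    def from_csv(cls, path, kind: Mapping[str, str]) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path), kind)


@dataclass
class ProblemInstance:
    """A minimum-set reserve-selection problem.

    Select planning units minimizing total cost subject to
    ``sum_i x_i r_ij >= T_j`` for every feature j, with locked-in units
    forced into and locked-out units forced out of any solution.
    """

    units: PlanningUnits
    features: FeatureTable
    targets: dict[str, float]
    locked_in: frozenset[int] = frozenset()
    locked_out: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.locked_in = frozenset(self.locked_in)
        self.locked_out = frozenset(self.locked_out)
        if self.locked_in & self.locked_out:
            raise ValueError("locked_in and locked_out overlap")
        avail = set(self.units.ids.tolist())
        if not self.locked_in <= avail or not self.locked_out <= avail:
            raise ValueError("locked units must be available planning units")
        for fid in self.features.feature_ids:
            if fid not in self.targets:
                raise KeyError(f"missing target for feature {fid!r}")
        for fid in self.targets:
            if fid not in self.features:
                raise KeyError(f"target for unknown feature {fid!r}")
            if not np.isfinite(self.targets[fid]):
                raise ValueError(f"non-finite target for {fid!r}")

    @property
    def n_units(self) -> int:
        return self.units.n_available

    @property
    def n_features(self) -> int:
        return len(self.features)

    def free_unit_ids(self) -> np.ndarray:
        locked = self.locked_in | self.locked_out
        ids = self.units.ids
        if not locked:
            return ids
        return ids[~np.isin(ids, list(locked))]

    def to_lp_text(self) -> str:
        """Plain-text LP-style listing for debugging."""
        flat_cost = self.units.cost.reshape(-1)
        lines = ["minimize"]
        lines.append("  " + " + ".join(
            f"{flat_cost[i]:g} x{i}" for i in self.units.ids))
        lines.append("subject to")
        for fid in self.features.feature_ids:
            amt = self.features.amounts(fid)
            expr = " + ".join(f"{a:g} x{u}" for u, a in sorted(amt.items()))
            lines.append(f"  [{fid}] {expr or '0'} >= {self.targets[fid]:g}")
        for u in sorted(self.locked_in):
            lines.append(f"  x{u} = 1")
        for u in sorted(self.locked_out):
            lines.append(f"  x{u} = 0")
        lines.append("binary " + " ".join(f"x{i}" for i in self.units.ids))
        return "\n".join(lines)


@dataclass
class Solution:
    """A (candidate) solution: binary selection with bookkeeping."""

    selected: frozenset[int]
    objective_km2: float
    attainment: dict[str, float]
    status: str  # optimal | feasible_gap | infeasible
    backend: str  # exact | greedy | brute_force
    gap: float = 0.0

    def __post_init__(self) -> None:
        self.selected = frozenset(self.selected)
        if self.status not in ("optimal", "feasible_gap", "infeasible"):
            raise ValueError(f"bad status {self.status!r}")
        if self.gap < 0:
            raise ValueError("gap must be nonnegative")

    def selection_layer(self, grid: GridSpec, name: str = "selection") -> Layer:
        vals = np.zeros(grid.shape, dtype=np.uint8)
        if self.selected:
            vals.reshape(-1)[list(self.selected)] = 1
        return Layer(grid, vals, name=name)

    def to_frame(self, units: PlanningUnits) -> pd.DataFrame:
        ids = units.ids
        return pd.DataFrame({
            "unit_id": ids,
            "selected": np.isin(ids, list(self.selected)).astype(int),
        })


def assemble_problem(
    ncp_layers: Sequence[Layer],
    species_aohs: Sequence,
    units: PlanningUnits,
    targets: Mapping[str, float],
    locked_in: Iterable[int] = (),
    locked_out: Iterable[int] = (),
) -> ProblemInstance:
    """Build a :class:`ProblemInstance` from value layers and AOH masks.

    NCP feature amounts are the per-cell NCP values on available units;
    species feature amounts are per-cell habitat area (``cell_area_km2`` on
    AOH cells, 0 elsewhere).  ``species_aohs`` accepts AOH objects (with
    ``.mask``/``.feature_id``) or boolean :class:`Layer` masks.
    """
    grid = units.grid
    _check_same_grid(ncp_layers, grid)
    ids = units.ids
    avail_flat = units.available.reshape(-1)

    ft = FeatureTable()
    for lyr in ncp_layers:
        vals = np.where(lyr.nodata, 0.0, lyr.values).reshape(-1)[ids]
        if np.any(vals < 0):
            raise ValueError(f"negative NCP value on available cell in {lyr.name!r}")
        ft.add_feature(lyr.name or f"ncp_{len(ft)}", "ncp", ids, vals)

    for obj in species_aohs:
        if hasattr(obj, "mask"):  # AOH
            mask_layer, fid = obj.mask, obj.feature_id
        else:
            mask_layer, fid = obj, obj.name
        if mask_layer.grid != grid:
            raise ValueError(f"AOH {fid!r} is not on the planning grid")
        m = (np.where(mask_layer.nodata, False, mask_layer.values.astype(bool))
             .reshape(-1)[ids])
        ft.add_feature(fid, "species", ids,
                       m.astype(float) * grid.cell_area_km2)

    unknown = set(targets) - set(ft.feature_ids)
    if unknown:
        raise KeyError(f"targets for unknown features: {sorted(unknown)}")
    problem = ProblemInstance(
        units=units,
        features=ft,
        targets={f: float(targets[f]) for f in ft.feature_ids},
        locked_in=frozenset(int(u) for u in locked_in if avail_flat[int(u)]),
        locked_out=frozenset(int(u) for u in locked_out),
    )
    return problem


def feasibility_check(problem: ProblemInstance) -> list[tuple[str, float]]:
    """Features whose target exceeds what is attainable even selecting
    every available, non-locked-out unit.  Empty list == feasible in
    principle."""
    out: list[tuple[str, float]] = []
    for fid in problem.features.feature_ids:
        total = problem.features.total_available(fid, exclude=problem.locked_out)
        deficit = problem.targets[fid] - total
        if deficit > 1e-9:
            out.append((fid, float(deficit)))
    return out


def verify_solution(problem: ProblemInstance,
                    solution: Solution) -> tuple[bool, list[str]]:
    """Check targets and lock constraints; returns (ok, violations)."""
    violations: list[str] = []
    avail = set(problem.units.ids.tolist())
    stray = solution.selected - avail
    if stray:
        raise ValueError(f"solution selects unavailable units {sorted(stray)[:5]}")
    for fid in problem.features.feature_ids:
        att = problem.features.attainment(fid, solution.selected)
        tgt = problem.targets[fid]
        if att < tgt - 1e-6 * max(1.0, abs(tgt)):
            violations.append(f"feature {fid}: attainment {att:g} < target {tgt:g}")
    missing = problem.locked_in - solution.selected
    if missing:
        violations.append(f"locked_in units not selected: {sorted(missing)}")
    stuck = problem.locked_out & solution.selected
    if stuck:
        violations.append(f"locked_out units selected: {sorted(stuck)}")
    return (not violations, violations)
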
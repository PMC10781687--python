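"""Scenario suite: protected-area preparation and lock-in, the NCP target
sweep with and without species, summed priority maps, area curves, and
coarse-to-fine habitat masking.

Solutions across levels are independent optimizations; nestedness is not
assumed (the summed map does not guarantee it either).  A cell counts as
protected when its PA coverage reaches ``lock_coverage_threshold``
(default 0.5, i.e. majority coverage; configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aoh_builder import AOH, build_aoh_set
from .core_model import (GridSpec, Layer, PlanningUnits, ProblemInstance,
                         Solution, assemble_problem)
from .optimizer import SolveOptions, solve
from .synthetic_landscape import PARecord, SyntheticLandscape
from .targets import TargetRuleParams, build_target_vector

DEFAULT_LEVELS: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 20))  # 5%..95% step 5%
DEFAULT_COMBINE_MAX_LEVEL = 0.90


@dataclass
class SweepResult:
    levels: list[float]
    solutions: list[Solution]
    include_species: bool
    locked_in_used: bool
    combined_priority: Layer
    area_curve: list[tuple[float, float]]  # (level, pct of land area)
    problem: ProblemInstance | None = field(default=None, repr=False)
    aohs: list[AOH] = field(default_factory=list, repr=False)

    def solution_at(self, level: float) -> Solution:
        for lv, sol in zip(self.levels, self.solutions):
            if abs(lv - level) < 1e-9:
                return sol
        raise KeyError(f"no solution at level {level}")

    def area_curve_frame(self) -> pd.DataFrame:
        rows = [(lv, pct, sol.status, sol.gap)
                for (lv, pct), sol in zip(self.area_curve, self.solutions)]
        return pd.DataFrame(rows, columns=["level", "pct_land_area",
                                           "status", "gap"])


def prepare_protected_areas(
    records: Sequence[PARecord],
    grid: GridSpec,
    lock_coverage_threshold: float = 0.5,
) -> tuple[Layer, set[int]]:
    """Filter PA records and rasterize them to a mask plus locked units.

    Records with proposed/unknown status or a UNESCO-MAB designation are
    dropped.  Point records become discs of radius ``sqrt(area / pi)``
    rasterized by cell-center inclusion.  ``locked_units`` are cells whose
    PA coverage meets the threshold.
    """
    if not 0.0 < lock_coverage_threshold <= 1.0:
        raise ValueError("lock_coverage_threshold must lie in (0, 1]")
    coverage = np.zeros(grid.shape)
    flat = coverage.reshape(-1)
    rows_idx, cols_idx = np.indices(grid.shape)
    for rec in records:
        if rec.status in ("proposed", "unknown"):
            continue
        if rec.designation == "UNESCO-MAB":
            continue
        if rec.geometry_kind == "point":
            if rec.reported_area_km2 <= 0:
                warnings.warn(f"PA record {rec.id}: nonpositive reported "
                              "area, rejected")
                continue
            radius_km = np.sqrt(rec.reported_area_km2 / np.pi)
            radius_cells = radius_km / grid.cell_side_km
            inside = ((rows_idx - rec.center[0]) ** 2
                      + (cols_idx - rec.center[1]) ** 2
                      <= radius_cells ** 2)
            coverage[inside] = 1.0
        else:
            if rec.cells:
                flat[list(rec.cells)] = 1.0
    pa_mask = Layer(grid, (coverage > 0).astype(np.uint8), name="pa_mask")
    locked = set(np.flatnonzero(
        coverage.reshape(-1) >= lock_coverage_threshold).tolist())
    return pa_mask, locked


def build_problem_from_landscape(
    landscape: SyntheticLandscape,
    locked_units: Iterable[int] = (),
) -> tuple[ProblemInstance, list[AOH], dict[str, float]]:
    """Assemble the planning problem for a landscape (targets all zero;
    use :func:`landprior.targets.build_target_vector` to set them)."""
    grid = landscape.grid
    units = PlanningUnits(grid, np.ones(grid.shape, dtype=bool))
    aohs = build_aoh_set(landscape.species, landscape.landcover,
                         landscape.elevation)
    zero = {lyr.name: 0.0 for lyr in landscape.ncp}
    zero.update({a.feature_id: 0.0 for a in aohs})
    problem = assemble_problem(landscape.ncp, aohs, units, zero,
                               locked_in=locked_units)
    species_areas = {a.feature_id: a.area_km2 for a in aohs}
    return problem, aohs, species_areas


def run_target_sweep(
    landscape: SyntheticLandscape,
    levels: Sequence[float] = DEFAULT_LEVELS,
    include_species: bool = True,
    locked_units: Iterable[int] = (),
    options: SolveOptions = SolveOptions(),
    rule_params: TargetRuleParams = TargetRuleParams(),
    combine_max_level: float = DEFAULT_COMBINE_MAX_LEVEL,
) -> SweepResult:
    """One exact solve per NCP level; species targets (when included) are
    identical across levels.  An infeasible level yields an infeasible
    Solution and the sweep continues."""
    levels = [float(lv) for lv in levels]
    if any(not 0.0 < lv <= 1.0 for lv in levels):
        raise ValueError("levels must lie in (0, 1]")
    if sorted(levels) != levels:
        raise ValueError("levels must be sorted ascending")

    problem, aohs, species_areas = build_problem_from_landscape(
        landscape, locked_units)
    total_area = problem.units.total_area_km2

    solutions: list[Solution] = []
    for lv in levels:
        targets = build_target_vector(problem.features, species_areas, lv,
                                      include_species, rule_params)
        lp = ProblemInstance(problem.units, problem.features, targets,
                             problem.locked_in, problem.locked_out)
        solutions.append(solve(lp, options))

    area_curve = [(lv, 100.0 * sol.objective_km2 / total_area)
                  for lv, sol in zip(levels, solutions)]
    result = SweepResult(
        levels=levels, solutions=solutions,
        include_species=include_species,
        locked_in_used=bool(set(locked_units)),
        combined_priority=Layer(landscape.grid,
                                np.zeros(landscape.grid.shape, dtype=np.int32),
                                name="combined_priority"),
        area_curve=area_curve, problem=problem, aohs=aohs)
    max_comb = (combine_max_level if any(lv <= combine_max_level + 1e-9
                                         for lv in levels) else levels[-1])
    # combine at the highest swept level not exceeding max_comb
    usable = [lv for lv in levels if lv <= max_comb + 1e-9]
    result.combined_priority = combine_solutions(result, usable[-1])
    return result


def combine_solutions(sweep: SweepResult, max_level: float) -> Layer:
    """Summed priority map: per-cell count of solutions (levels up to
    ``max_level``) selecting the cell.  Low positive values mark cells
    needed even at the lowest targets."""
    if not any(abs(lv - max_level) < 1e-9 for lv in sweep.levels):
        raise ValueError(f"sweep has no solution at level {max_level}")
    grid = sweep.combined_priority.grid if sweep.problem is None \
        else sweep.problem.units.grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    flat = counts.reshape(-1)
    for lv, sol in zip(sweep.levels, sweep.solutions):
        if lv <= max_level + 1e-9 and sol.status != "infeasible":
            if sol.selected:
                flat[list(sol.selected)] += 1
    return Layer(grid, counts, name="combined_priority")


def species_required_cells(coarse_solution: Solution, fine_habitat: Layer,
                           factor: int) -> set[int]:
    """Coarse selected cells with zero fine natural-habitat coverage —
    the cells whose species rely on deserts or human-modified habitat and
    would vanish under a pure habitat mask."""
    fg = fine_habitat.grid
    nr, nc = fg.n_rows // factor, fg.n_cols // factor
    hab = (fine_habitat.values.astype(bool) & fine_habitat.valid)
    block_any = (hab.reshape(nr, factor, nc, factor)
                 .swapaxes(1, 2).any(axis=(2, 3)))
    out = set()
    for u in coarse_solution.selected:
        r, c = divmod(u, nc)
        if not block_any[r, c]:
            out.add(u)
    return out


def mask_to_habitat(coarse_solution: Solution, fine_habitat: Layer,
                    factor: int,
                    species_required: Iterable[int] = ()) -> Layer:
    """Downscale a coarse selection to fine natural habitat.

    The fine mask is the upsampled coarse selection intersected with
    ``fine_habitat``; every fine cell of a coarse selected cell listed in
    ``species_required`` is then re-included wholesale.
    """
    fg = fine_habitat.grid
    if fg.n_rows % factor or fg.n_cols % factor:
        raise ValueError("fine grid is not a multiple of the factor")
    nr, nc = fg.n_rows // factor, fg.n_cols // factor
    coarse_sel = np.zeros((nr, nc), dtype=bool)
    flat = coarse_sel.reshape(-1)
    sel = list(coarse_solution.selected)
    if sel and max(sel) >= nr * nc:
        raise ValueError("coarse selection does not fit the implied grid")
    if sel:
        flat[sel] = True
    up = np.kron(coarse_sel, np.ones((factor, factor), dtype=bool))
    hab = fine_habitat.values.astype(bool) & fine_habitat.valid
    fine_mask = up & hab
    required = set(species_required) & coarse_solution.selected
    for u in required:
        r, c = divmod(u, nc)
        fine_mask[r * factor:(r + 1) * factor,
                  c * factor:(c + 1) * factor] = True
    return Layer(fg, fine_mask.astype(np.uint8), name="priority_fine")
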
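"""Configuration, raster/table I/O, and the end-to-end pipeline.

Rasters are single-band ESRI ASCII grids (``.asc``): a plain-text,
GDAL-compatible format whose header carries the grid dimensions and cell
size (here in km).  Values print with 17 significant digits so float64
round-trips are lossless; the nodata sentinel is -9999.

``run_pipeline`` composes the stages — simulate → AOH → targets → sweep
(± species, ± protected-area lock-in) → combined priority map →
development-pressure classification → overlay report — and writes a
manifest with the seed, package version, instance sizes, and per-file
SHA-256 checksums.  With exact solving (gap 0) the whole run is
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .aoh_builder import aoh_summary
from .core_model import GridSpec, Layer
from .development_pressure import bin_counts_frame, classify_dpi, combine_pressure
from .optimizer import SolveOptions
from .overlay_report import overlap_stats, strata_from_categorical
from .scenarios import (DEFAULT_LEVELS, SweepResult, prepare_protected_areas,
                        run_target_sweep)
from .synthetic_landscape import LandscapeParams, generate_landscape
from .targets import TargetRuleParams, build_target_vector, targets_to_frame

NODATA_VALUE = -9999.0


# --------------------------------------------------------------------------
# raster I/O

def write_layer(layer: Layer, path) -> Path:
    """Write a layer as an ESRI ASCII grid (cellsize in km)."""
    path = Path(path)
    g = layer.grid
    vals = np.where(layer.nodata, NODATA_VALUE,
                    layer.values.astype(float))
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {g.cell_side_km!r}\n")
        fh.write(f"NODATA_value {NODATA_VALUE:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_layer(path, expected_grid: GridSpec | None = None) -> Layer:
    """Read an ESRI ASCII grid written by :func:`write_layer`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid {path}: missing {key}")
    grid = GridSpec(int(header["nrows"]), int(header["ncols"]),
                    header["cellsize"])
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"{path}: grid {grid} != expected {expected_grid}")
    vals = np.loadtxt(lines[n_header:], ndmin=2)
    if vals.shape != grid.shape:
        raise ValueError(f"{path}: data shape {vals.shape} != header grid")
    nodata_val = header.get("nodata_value", NODATA_VALUE)
    nodata = vals == nodata_val
    vals = np.where(nodata, 0.0, vals)
    return Layer(grid, vals, nodata=nodata, name=path.stem)


# --------------------------------------------------------------------------
# configuration

_CONFIG_FIELDS = {
    "n_rows", "n_cols", "cell_side_km", "n_ncp", "n_species", "n_countries",
    "n_biomes", "pa_fraction", "n_sectors", "autocorrelation_length_cells",
    "migratory_fraction", "levels", "include_species", "lock_pas",
    "lock_coverage_threshold", "relative_gap", "time_limit_s", "seed",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (YAML/JSON loadable)."""

    n_rows: int = 30
    n_cols: int = 30
    cell_side_km: float = 10.0
    n_ncp: int = 10
    n_species: int = 20
    n_countries: int = 4
    n_biomes: int = 3
    pa_fraction: float = 0.12
    n_sectors: int = 14
    autocorrelation_length_cells: float = 3.0
    migratory_fraction: float = 0.2
    levels: list[float] = field(default_factory=lambda: list(DEFAULT_LEVELS))
    include_species: bool | str = True  # True | False | "both"
    lock_pas: bool = True
    lock_coverage_threshold: float = 0.5
    relative_gap: float = 0.0
    time_limit_s: float | None = None
    seed: int = 0
    out_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.include_species not in (True, False, "both"):
            raise ValueError('include_species must be true, false or "both"')
        if any(not 0.0 < lv <= 1.0 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def landscape_params(self) -> LandscapeParams:
        return LandscapeParams(
            grid=GridSpec(self.n_rows, self.n_cols, self.cell_side_km),
            n_ncp=self.n_ncp, n_species=self.n_species,
            n_countries=self.n_countries, n_biomes=self.n_biomes,
            pa_fraction=self.pa_fraction, n_sectors=self.n_sectors,
            autocorrelation_length_cells=self.autocorrelation_length_cells,
            migratory_fraction=self.migratory_fraction, seed=self.seed)


# --------------------------------------------------------------------------
# pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_sweep(out: Path, tag: str, sweep: SweepResult,
                 manifest_files: list[Path]) -> None:
    curve_path = out / f"area_curve_{tag}.csv"
    sweep.area_curve_frame().to_csv(curve_path, index=False)
    manifest_files.append(curve_path)
    manifest_files.append(
        write_layer(sweep.combined_priority,
                    out / f"combined_priority_{tag}.asc"))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    options = SolveOptions(relative_gap=config.relative_gap,
                           time_limit_s=config.time_limit_s)
    rule = TargetRuleParams()

    # 1. simulate
    params = config.landscape_params()
    landscape = generate_landscape(params)
    for lyr in (landscape.landcover, landscape.elevation,
                landscape.countries, landscape.biomes):
        files.append(write_layer(lyr, out / f"{lyr.name}.asc"))

    # 2. protected areas
    pa_mask, locked = prepare_protected_areas(
        landscape.pa_records, landscape.grid,
        config.lock_coverage_threshold)
    files.append(write_layer(pa_mask, out / "pa_mask.asc"))

    # 3-4. sweeps (AOH and targets are built inside run_target_sweep)
    species_modes = ([True, False] if config.include_species == "both"
                     else [bool(config.include_species)])
    sweeps: dict[str, SweepResult] = {}
    for with_species in species_modes:
        tag = "species" if with_species else "ncp_only"
        sweeps[tag] = run_target_sweep(
            landscape, config.levels, include_species=with_species,
            options=options, rule_params=rule)
        _write_sweep(out, tag, sweeps[tag], files)
        if config.lock_pas:
            tag_l = f"{tag}_locked"
            sweeps[tag_l] = run_target_sweep(
                landscape, config.levels, include_species=with_species,
                locked_units=locked, options=options, rule_params=rule)
            _write_sweep(out, tag_l, sweeps[tag_l], files)

    primary = sweeps[next(iter(sweeps))]
    aoh_path = out / "aoh_summary.csv"
    aoh_summary(primary.aohs).to_csv(aoh_path, index=False)
    files.append(aoh_path)

    species_areas = {a.feature_id: a.area_km2 for a in primary.aohs}
    ref_level = max(lv for lv in config.levels)
    targets = build_target_vector(primary.problem.features, species_areas,
                                  ref_level, True, rule)
    tgt_path = out / "targets.csv"
    targets_to_frame(targets, primary.problem.features,
                     species_areas, rule).to_csv(tgt_path, index=False)
    files.append(tgt_path)

    if len(species_modes) == 2:
        cmp_rows = []
        for lv in config.levels:
            cmp_rows.append({
                "level": lv,
                "pct_land_species":
                    dict(sweeps["species"].area_curve)[lv],
                "pct_land_ncp_only":
                    dict(sweeps["ncp_only"].area_curve)[lv],
            })
        cmp_path = out / "species_vs_ncp_only.csv"
        pd.DataFrame(cmp_rows).to_csv(cmp_path, index=False)
        files.append(cmp_path)

    # 5. development pressure
    categories = [classify_dpi(d, landscape.countries) for d in landscape.dpi]
    pressure = combine_pressure(categories)
    files.append(write_layer(pressure.combined, out / "pressure_combined.asc"))
    files.append(write_layer(pressure.high_mask, out / "pressure_high.asc"))
    bins_path = out / "pressure_bins.csv"
    bin_counts_frame(pressure, landscape.countries).to_csv(bins_path,
                                                           index=False)
    files.append(bins_path)

    # 6. overlay at the reference level (highest level <= 0.90 if present)
    overlay_levels = [lv for lv in config.levels if lv <= 0.90 + 1e-9]
    overlay_level = overlay_levels[-1] if overlay_levels else config.levels[-1]
    sol = primary.solution_at(overlay_level)
    priority = sol.selection_layer(landscape.grid, name="priority")
    strata = {}
    strata.update(strata_from_categorical(landscape.countries, "country_"))
    strata.update(strata_from_categorical(landscape.biomes, "biome_"))
    per_sector_high = {
        name: Layer(landscape.grid,
                    (lyr.values >= 5).astype(np.uint8) * lyr.valid,
                    name=name)
        for name, lyr in pressure.sectors.items()}
    report = overlap_stats(priority, pa_mask, pressure.high_mask,
                           strata=strata, per_sector_high=per_sector_high)
    report_path = out / "overlap_report.json"
    report.to_json(report_path)
    files.append(report_path)
    files.append(write_layer(priority, out / "priority.asc"))

    # 7. manifest
    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "instance": {
            "n_units": primary.problem.n_units,
            "n_features": primary.problem.n_features,
            "n_levels": len(config.levels),
            "overlay_level": overlay_level,
        },
        "checksums": {p.name: _sha256(p) for p in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
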
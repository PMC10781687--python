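"""Seeded synthetic landscapes with the statistical structure the
prioritization pipeline assumes.

The generator emulates the *structure* of the global inputs — positive,
spatially autocorrelated NCP surfaces attributed only to natural and
semi-natural landcover; species ranges spanning restricted to wide with
habitat-class and elevational preferences; patchy protected areas
including point records and proposed/UNESCO designations; and per-sector
0–1 development-suitability surfaces with constraint masks — not any
real-world geography.  Everything is deterministic given the seed.

Random fields are built by Gaussian-smoothing white noise with a kernel of
width ``autocorrelation_length_cells`` and exponentiating to enforce
positivity, which yields the skewed positive surfaces typical of mapped
ecosystem services.  Countries and biomes are contiguous Voronoi
partitions of the grid, needed for per-country z-scoring and stratified
reporting.  A ``population_proxy`` layer (smoothed point clusters) lets
beneficiary-weighted NCP be emulated by multiplying a raw surface by
proximity to population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_model import GridSpec, Layer


class GenerationError(RuntimeError):
    """Raised when the requested landscape cannot be generated."""


@dataclass(frozen=True)
class LandcoverClass:
    code: int
    name: str
    role: str  # natural | semi_natural | developed | unvegetated

    def __post_init__(self) -> None:
        if self.role not in ("natural", "semi_natural", "developed", "unvegetated"):
            raise ValueError(f"unknown landcover role {self.role!r}")


DEFAULT_LANDCOVER: tuple[LandcoverClass, ...] = (
    LandcoverClass(1, "forest", "natural"),
    LandcoverClass(2, "shrubland", "natural"),
    LandcoverClass(3, "wetland", "natural"),
    LandcoverClass(4, "grassland", "semi_natural"),
    LandcoverClass(5, "cropland", "developed"),
    LandcoverClass(6, "urban", "developed"),
    LandcoverClass(7, "bare", "unvegetated"),
)

DEFAULT_SECTORS: tuple[str, ...] = (
    "crop_agriculture", "biofuels",
    "solar_csp", "solar_pv", "wind", "hydropower",
    "oil_conventional", "oil_unconventional",
    "gas_conventional", "gas_unconventional",
    "mining_metallic", "mining_nonmetallic", "mining_coal",
    "urban",
)

PA_STATUSES = ("designated", "inscribed", "established", "proposed", "unknown")


@dataclass(frozen=True)
class LandscapeParams:
    """Knobs of the synthetic landscape generator.

    Defaults describe the study conditions the pipeline targets: ten NCP
    layers, fourteen development sectors, landcover with natural,
    semi-natural, developed and unvegetated roles, and protected areas
    covering roughly ``pa_fraction`` of the land.
    """

    grid: GridSpec = GridSpec(40, 40, 10.0)
    n_ncp: int = 10
    n_species: int = 30
    n_countries: int = 5
    n_biomes: int = 4
    landcover_classes: tuple[LandcoverClass, ...] = DEFAULT_LANDCOVER
    elevation_range_m: tuple[float, float] = (0.0, 3000.0)
    pa_fraction: float = 0.12
    n_sectors: int = 14
    sector_names: tuple[str, ...] = DEFAULT_SECTORS
    autocorrelation_length_cells: float = 3.0
    migratory_fraction: float = 0.2
    proposed_rate: float = 0.10
    unknown_rate: float = 0.05
    unesco_rate: float = 0.05
    point_record_rate: float = 0.25
    dpi_constraint_fraction: float = 0.15
    beneficiary_weighted_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ncp < 1:
            raise ValueError("n_ncp must be >= 1")
        for frac in (self.pa_fraction, self.migratory_fraction,
                     self.proposed_rate, self.unknown_rate, self.unesco_rate,
                     self.point_record_rate, self.dpi_constraint_fraction,
                     self.beneficiary_weighted_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.autocorrelation_length_cells <= 0:
            raise ValueError("autocorrelation_length_cells must be positive")
        if len(self.sector_names) < self.n_sectors:
            raise ValueError("not enough sector names for n_sectors")

    @property
    def natural_codes(self) -> frozenset[int]:
        """Codes of natural + semi-natural classes (NCP-bearing habitat)."""
        return frozenset(c.code for c in self.landcover_classes
                         if c.role in ("natural", "semi_natural"))


@dataclass(frozen=True)
class SpeciesTrait:
    """One species record: taxon, habitat/elevation preferences, range."""

    species_id: str
    taxon: str  # bird | mammal | reptile | amphibian
    habitat_codes: frozenset[int]
    elevation_min_m: float
    elevation_max_m: float
    seasonal_code: int  # 1 year-round, 2 breeding, 3 non-breeding (birds)
    range_mask: Layer

    def __post_init__(self) -> None:
        if self.elevation_min_m > self.elevation_max_m:
            raise ValueError("elevation_min_m > elevation_max_m")
        if not self.habitat_codes:
            raise ValueError("habitat_codes must be nonempty")
        if self.seasonal_code not in (1, 2, 3):
            raise ValueError("seasonal_code must be 1, 2 or 3")
        if self.taxon != "bird" and self.seasonal_code != 1:
            raise ValueError("only birds carry seasonal codes 2/3")


@dataclass(frozen=True)
class PARecord:
    """One protected-area register entry (polygon mask or point locality)."""

    id: str
    geometry_kind: str  # polygon_mask | point
    status: str
    designation: str = ""
    cells: frozenset[int] = frozenset()       # polygon_mask records
    center: tuple[int, int] = (0, 0)          # point records (row, col)
    reported_area_km2: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry_kind not in ("polygon_mask", "point"):
            raise ValueError(f"bad geometry_kind {self.geometry_kind!r}")
        if self.status not in PA_STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.geometry_kind == "point" and self.reported_area_km2 <= 0:
            raise ValueError("point records need a positive reported area")


@dataclass
class SyntheticLandscape:
    params: LandscapeParams
    landcover: Layer
    elevation: Layer
    countries: Layer
    biomes: Layer
    population_proxy: Layer
    ncp: list[Layer]
    species: list[SpeciesTrait]
    pa_records: list[PARecord]
    dpi: list[Layer]

    @property
    def grid(self) -> GridSpec:
        return self.params.grid

    def natural_mask(self) -> np.ndarray:
        codes = sorted(self.params.natural_codes)
        return np.isin(self.landcover.values, codes)


# --------------------------------------------------------------------------
# field helpers

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ~length."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=length, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _voronoi_partition(rng: np.random.Generator, grid: GridSpec,
                       n_regions: int, name: str) -> Layer:
    rows, cols = np.indices(grid.shape)
    seeds_r = rng.uniform(0, grid.n_rows, n_regions)
    seeds_c = rng.uniform(0, grid.n_cols, n_regions)
    d2 = ((rows[..., None] - seeds_r) ** 2 + (cols[..., None] - seeds_c) ** 2)
    return Layer(grid, np.argmin(d2, axis=-1).astype(np.int32) + 1, name=name)


def _disc_cells(grid: GridSpec, center: tuple[int, int],
                radius_cells: float) -> np.ndarray:
    rows, cols = np.indices(grid.shape)
    return ((rows - center[0]) ** 2 + (cols - center[1]) ** 2
            <= radius_cells ** 2)


# --------------------------------------------------------------------------
# generators

def _generate_landcover(rng: np.random.Generator,
                        params: LandscapeParams) -> Layer:
    classes = params.landcover_classes
    if not any(c.role in ("natural", "semi_natural") for c in classes):
        raise GenerationError("landscape needs at least one natural class")
    # one smoothed field per class; mild bias toward natural roles so NCP
    # surfaces have support
    bias = {"natural": 0.5, "semi_natural": 0.3,
            "developed": 0.0, "unvegetated": -0.2}
    fields = np.stack([
        _smooth_field(rng, params.grid.shape,
                      params.autocorrelation_length_cells) + bias[c.role]
        for c in classes
    ])
    winner = np.argmax(fields, axis=0)
    codes = np.array([c.code for c in classes], dtype=np.int32)
    lc = Layer(params.grid, codes[winner], name="landcover")
    if not np.isin(lc.values, sorted(params.natural_codes)).any():
        raise GenerationError("generated landcover has no natural cells")
    return lc


def _generate_population(rng: np.random.Generator,
                         params: LandscapeParams) -> Layer:
    grid = params.grid
    n_clusters = max(2, grid.n_cells // 300)
    density = np.zeros(grid.shape)
    flat_idx = rng.choice(grid.n_cells, size=n_clusters, replace=False)
    density.reshape(-1)[flat_idx] = rng.gamma(2.0, 50.0, n_clusters)
    density = gaussian_filter(density, sigma=params.autocorrelation_length_cells,
                              mode="reflect")
    return Layer(grid, density, name="population_proxy")


def _generate_ncp(rng: np.random.Generator, params: LandscapeParams,
                  natural: np.ndarray, population: Layer) -> list[Layer]:
    layers = []
    pop = population.values
    pop_norm = pop / pop.max() if pop.max() > 0 else pop
    for k in range(params.n_ncp):
        f = _smooth_field(rng, params.grid.shape,
                          params.autocorrelation_length_cells)
        vals = np.exp(f)  # skewed positive surface
        if k < round(params.beneficiary_weighted_fraction * params.n_ncp):
            vals = vals * (0.1 + pop_norm)  # beneficiary-weighted flavor
        vals = np.where(natural, vals, 0.0)
        layers.append(Layer(params.grid, vals, name=f"ncp_{k:02d}"))
    return layers


def generate_species_set(params: LandscapeParams, landcover: Layer,
                         elevation: Layer,
                         rng: np.random.Generator) -> list[SpeciesTrait]:
    """Draw ``n_species`` species with ranges from restricted to wide.

    Range centers sit on natural/semi-natural cells; habitat codes are
    drawn from the natural classes present in each range; elevational
    limits are a quantile band of elevations inside the range, so AOH are
    usually (not always) nonempty.  A ``migratory_fraction`` of bird
    species is emitted as two records with seasonal codes 2 and 3.
    """
    grid = params.grid
    natural_codes = sorted(params.natural_codes)
    natural_flat = np.flatnonzero(
        np.isin(landcover.values, natural_codes).reshape(-1))
    if natural_flat.size == 0:
        raise GenerationError("no natural cells to host species ranges")

    max_radius = max(1.0, 0.6 * max(grid.n_rows, grid.n_cols))
    taxa = ("bird", "mammal", "reptile", "amphibian")
    out: list[SpeciesTrait] = []
    for s in range(params.n_species):
        taxon = taxa[int(rng.integers(len(taxa)))]
        center_flat = int(rng.choice(natural_flat))
        center = divmod(center_flat, grid.n_cols)
        # log-uniform radii: many restricted-range, few wide-ranging
        radius = float(np.exp(rng.uniform(0.0, np.log(max_radius))))
        mask = _disc_cells(grid, center, radius)
        if not mask.any():  # pragma: no cover - disc always holds its center
            raise GenerationError("empty species range generated")

        in_range_codes = [c for c in natural_codes
                          if np.isin(landcover.values[mask], c).any()]
        if not in_range_codes:
            in_range_codes = natural_codes
        n_codes = int(rng.integers(1, len(in_range_codes) + 1))
        habitat = frozenset(
            int(c) for c in rng.choice(in_range_codes, n_codes, replace=False))

        elevs = elevation.values[mask]
        qlo = float(rng.uniform(0.0, 0.3))
        qhi = float(rng.uniform(0.7, 1.0))
        emin, emax = np.quantile(elevs, [qlo, qhi])

        sid = f"sp_{s:04d}"
        range_layer = Layer(grid, mask.astype(np.uint8), name=f"{sid}_range")
        if taxon == "bird" and rng.random() < params.migratory_fraction:
            for code in (2, 3):
                out.append(SpeciesTrait(sid, taxon, habitat,
                                        float(emin), float(emax), code,
                                        range_layer))
        else:
            out.append(SpeciesTrait(sid, taxon, habitat,
                                    float(emin), float(emax), 1, range_layer))
    return out


def generate_pa_records(params: LandscapeParams,
                        rng: np.random.Generator,
                        n_records: int | None = None) -> list[PARecord]:
    """Draw a register of protected-area records.

    A mixture of polygon-mask and point records whose union covers roughly
    ``pa_fraction`` of the grid; statuses include proposed/unknown and
    designations include "UNESCO-MAB" at configurable rates so the filter
    rules are exercisable.
    """
    grid = params.grid
    if params.pa_fraction == 0.0 and n_records is None:
        return []
    cell_area = grid.cell_area_km2
    mean_patch_cells = max(2.0, 0.004 * grid.n_cells)
    if n_records is None:
        n_records = max(1, int(round(params.pa_fraction * grid.n_cells
                                     / mean_patch_cells)))
    records: list[PARecord] = []
    for k in range(n_records):
        u = rng.random()
        if u < params.proposed_rate:
            status = "proposed"
        elif u < params.proposed_rate + params.unknown_rate:
            status = "unknown"
        else:
            status = str(rng.choice(["designated", "inscribed", "established"],
                                    p=[0.8, 0.1, 0.1]))
        designation = "UNESCO-MAB" if rng.random() < params.unesco_rate else ""
        center = (int(rng.integers(grid.n_rows)), int(rng.integers(grid.n_cols)))
        area_cells = float(rng.gamma(2.0, mean_patch_cells / 2.0)) + 0.5
        if rng.random() < params.point_record_rate:
            records.append(PARecord(
                id=f"pa_{k:04d}", geometry_kind="point", status=status,
                designation=designation, center=center,
                reported_area_km2=area_cells * cell_area))
        else:
            radius = np.sqrt(area_cells / np.pi)
            cells = frozenset(
                np.flatnonzero(_disc_cells(grid, center, radius).reshape(-1))
                .tolist())
            records.append(PARecord(
                id=f"pa_{k:04d}", geometry_kind="polygon_mask", status=status,
                designation=designation, cells=cells,
                reported_area_km2=len(cells) * cell_area))
    return records


def _generate_dpi(rng: np.random.Generator,
                  params: LandscapeParams) -> list[Layer]:
    """Per-sector 0–1 suitability surfaces with constraint (nodata) masks.

    Sectors share a common accessibility/terrain backbone so that
    high-suitability areas cluster across sectors rather than tiling the
    whole grid, as published suitability layers do.
    """
    layers = []
    backbone = _smooth_field(rng, params.grid.shape,
                             params.autocorrelation_length_cells)
    for name in params.sector_names[: params.n_sectors]:
        own = _smooth_field(rng, params.grid.shape,
                            params.autocorrelation_length_cells)
        f = 0.75 * backbone + 0.66 * own
        # rank-normalize to [0, 1]
        flat = f.reshape(-1)
        ranks = np.argsort(np.argsort(flat))
        vals = (ranks / max(1, flat.size - 1)).reshape(params.grid.shape)
        constraint = _smooth_field(rng, params.grid.shape,
                                   params.autocorrelation_length_cells)
        cut = np.quantile(constraint, 1.0 - params.dpi_constraint_fraction)
        nodata = constraint > cut
        layers.append(Layer(params.grid, vals, nodata=nodata,
                            name=f"dpi_{name}"))
    return layers


def generate_landscape(params: LandscapeParams) -> SyntheticLandscape:
    """Generate a full synthetic landscape, deterministic given the seed."""
    ss = np.random.SeedSequence(params.seed)
    (r_lc, r_elev, r_part, r_pop, r_ncp,
     r_species, r_pa, r_dpi) = [np.random.default_rng(s) for s in ss.spawn(8)]

    grid = params.grid
    landcover = _generate_landcover(r_lc, params)

    lo, hi = params.elevation_range_m
    ef = _smooth_field(r_elev, grid.shape, params.autocorrelation_length_cells)
    ef = (ef - ef.min()) / max(np.ptp(ef), 1e-12)
    elevation = Layer(grid, lo + ef * (hi - lo), name="elevation")

    countries = _voronoi_partition(r_part, grid, params.n_countries, "countries")
    biomes = _voronoi_partition(r_part, grid, params.n_biomes, "biomes")
    population = _generate_population(r_pop, params)

    natural = np.isin(landcover.values, sorted(params.natural_codes))
    ncp = _generate_ncp(r_ncp, params, natural, population)
    species = generate_species_set(params, landcover, elevation, r_species)
    pa_records = generate_pa_records(params, r_pa)
    dpi = _generate_dpi(r_dpi, params)

    return SyntheticLandscape(
        params=params, landcover=landcover, elevation=elevation,
        countries=countries, biomes=biomes, population_proxy=population,
        ncp=ncp, species=species, pa_records=pa_records, dpi=dpi)
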
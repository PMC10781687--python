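# Methods

## The planning problem

All computation happens on an abstract equal-area lattice (`GridSpec`):
`n_rows × n_cols` square cells of side `cell_side_km` (default 10 km,
cell area 100 km²).  Unit ids are 0-based, row-major; every module uses
that convention.  Planning-unit cost is the cell's land area, so the
objective is minimum total area — the standard stand-in when opportunity
costs are unavailable or distrusted.  A cost layer can be substituted, but
none of the shipped analyses do.

A problem instance holds sparse feature amounts `r_ij`: for an NCP
feature, the layer's per-cell value; for a species feature, the cell area
on the species' Area-of-Habitat (AOH) cells and zero elsewhere.  Targets
are compared against attainment in the same units (NCP units or km²).
Locked-in units (protected areas) are forced into the solution, locked-out
units excluded; infeasibility is diagnosed per feature before solving.

## Species representation targets

The target fraction of a species' AOH area `A` (km²) is

* `f(A) = 1` for `A ≤ 1,000`,
* `f(A) = 0.10` for `A ≥ 250,000`,
* log-linear in between: `f(A) = 1 − 0.9·(ln A − ln 1000)/ln 250`
  (base-invariant),

and the target area is `min(f(A)·A, 1,000,000 km²)`; under these defaults
the cap binds exactly when `A > 10,000,000 km²`.  Boundary assignment: at
`A = 1,000` the interpolant applies (equals 1.0); at `A = 250,000` the
floor applies (0.10) — continuity makes the choice immaterial, stating it
removes ambiguity.  Seasonal bird distributions (codes 2 = breeding,
3 = non-breeding) are separate features with independently derived
targets; NCP targets are `level × total`, and species targets do not vary
with the NCP level.

**Known quirk, asserted in the tests rather than hidden:** the absolute
target `A·f(A)` is *not* monotone in `A`.  Its derivative is
`f(A) − 0.9/ln 250 ≈ f(A) − 0.163`, which is negative once `f < 0.163`,
i.e. for `A` between ≈170,000 and 250,000 km²: the target declines from
≈27,690 km² to 25,000 km² (a ≈9.7% dip) before the 10% floor resumes
growth.  This is a property of interpolating the *fraction* log-linearly
between the published knots — the rule this package implements — not an
implementation artifact.  The unit suite pins the dip's analytic location
and depth; one acceptance-style test asserts blanket monotonicity and
therefore fails, deliberately, as documentation.

## Solvers

Three backends share one contract (selection, objective, per-feature
attainment, status, gap):

* **exact** — mixed-integer programming via HiGHS (`scipy.optimize.milp`),
  default relative gap 0.  On equal-cost instances the objective is
  integral in units of one cell cost, so the solver also receives an
  absolute MIP gap of 0.999 cells: terminating there proves the optimal
  objective value while skipping the symmetric branch-and-bound tail that
  plagues minimum-set instances (many interchangeable optimal cells).
  Such terminations are reported as `optimal`, gap 0, because the
  objective value is proven.  With a `time_limit_s`, an unproven incumbent
  is returned honestly as `feasible_gap` with its relative gap.
* **greedy** — iteratively adds the unit maximizing
  `Σ_j min(r_ij, remaining deficit_j)/c_i`, ties to the lowest unit id;
  feasible whenever the problem is, never better than exact.
* **brute_force** — vectorized enumeration of all subsets of ≤20 free
  units; ties break to the lexicographically smallest sorted selection.
  This is the test oracle for the exact backend.

A note on hardness: minimum-set instances with equal costs can stall on a
one-cell bound plateau.  On the shipped 40×40 study landscape, the
NCP-only problem at the 60% level has LP bound 527.95 cells and an
incumbent of 529; deciding 528 vs 529 exceeded four minutes in either
direction (feasibility probe and proof both).  The sweep therefore accepts
a per-solve wall cap (60 s in the analysis drivers and acceptance suite);
capped levels keep their incumbent, flagged `feasible_gap`, and the area
curves report status per level.  All NCP+species levels on the study
landscape prove optimal in under a second each.

## Synthetic landscapes

The generator emulates the statistical structure of the global inputs,
never their geography:

* **Random fields.** White noise smoothed with a Gaussian kernel of width
  `autocorrelation_length_cells` (default 3), exponentiated where
  positivity and right-skew are wanted (NCP surfaces).  All NCP values are
  ≥ 0 and exactly 0 on developed and unvegetated landcover — services are
  attributed only to the natural and semi-natural classes providing them.
  Half the NCP layers (configurable) are multiplied by proximity to
  population clusters to emulate beneficiary weighting.
* **Landcover.** Per-class smoothed fields with role-dependent bias,
  argmax per cell; seven default classes spanning natural, semi-natural,
  developed and unvegetated roles.
* **Strata.** Countries and biomes are contiguous Voronoi partitions —
  enough structure for per-country z-scoring and stratified reporting.
* **Species.** Range discs centred on natural cells with log-uniform radii
  (many restricted-range, few wide-ranging); habitat codes drawn from
  natural classes present in the range; elevational limits a quantile band
  of in-range elevations; a `migratory_fraction` of birds (default 0.2)
  emitted as two seasonal records.
* **Protected areas.** A register of polygon-mask and point records with
  configurable rates of proposed/unknown status and UNESCO-MAB
  designation, sized so filtered coverage lands near `pa_fraction`
  (default 0.12).
* **Development suitability.** Fourteen 0–1 sector surfaces sharing a
  common smoothed backbone (weight 0.75) plus sector-specific fields, so
  high-suitability areas cluster across sectors as published layers do;
  each carries a constraint (nodata) mask (default 15% of cells).

Everything derives from one `SeedSequence`; regeneration is bit-identical
per seed.  What the generator does **not** emulate: coastlines or any real
geography, realistic NCP inter-correlations, range-shape complexity,
actual protection siting bias.  Passing tests therefore demonstrate the
pipeline's contracts (dominance, monotonicity, partitioning, determinism)
— not that real-world percentages would take similar values.

## Stage-specific choices

* **Majority aggregation** (fine landcover → planning grid): modal class
  per block, nodata excluded, all-nodata block → nodata, ties to the
  lowest class code (deterministic; the choice is otherwise arbitrary).
  Grid dimensions must divide evenly — no partial blocks.
* **Elevational filtering** is inclusive at both bounds.
* **PA preparation**: records with proposed/unknown status or UNESCO-MAB
  designation are dropped; point records become discs of radius
  `sqrt(area/π)` rasterized by cell-center inclusion.  Per-cell coverage
  is thus binary, and a cell is locked when coverage ≥
  `lock_coverage_threshold` (default 0.5 — majority coverage, the
  conventional rule where the source analyses leave it unstated).
* **Pressure classification**: z-scores per country; empirical
  nearest-rank percentiles at 10/25/50/75/90 define six categories with
  closed-left endpoints, so ties can only demote a cell.  Countries with
  fewer than two valid cells or zero variance collapse to category 1 with
  a warning.  Cut-points are per-country by default; a `global_bins`
  option pools them.  Classification is invariant to positive affine
  rescaling of a country's values.
* **Summed priority maps** combine independent per-level solutions
  (default levels ≤ 90%); nestedness across levels is not assumed and not
  guaranteed.
* **Coarse-to-fine masking** intersects the upsampled selection with fine
  natural habitat, then re-includes wholesale the fine cells of selected
  coarse cells that have *zero* fine habitat — the operationalization of
  keeping desert- and modified-habitat species in the map.
* **Overlay arithmetic** is cell counting × cell area; percentages are
  rounded to one decimal for presentation while raw fractions stay in the
  machine-readable report.  Both denominators (prioritized area, total
  land) are always reported.

## Numerical and I/O details

Rasters serialize as ESRI ASCII grids (text, GDAL-compatible) with
17-significant-digit values and nodata sentinel −9999; cell size is in
km.  Feature tables, targets, area curves and bin counts are plain CSV;
the overlay report is JSON.  `run_pipeline` writes a manifest with the
seed, configuration, instance sizes and SHA-256 checksums of every
output; with exact solving the whole run is deterministic given the seed,
and the determinism test asserts checksum equality across repeated runs.

## Problem sizes

The shipped study landscape is 40×40 cells (1,600 planning units) with
ten NCP layers and thirty species (≈31–41 features after seasonal
splitting), swept over 19 target levels per scenario; unit tests use
12–20-cell grids and ≤18-unit instances where exhaustive enumeration is
the oracle.  These sizes keep every stage's exact optimization honest
(proven gaps, not heuristics) while the full suite runs in minutes.

## Limitations

Beyond the synthetic-data caveats above: no connectivity, intactness or
ecosystem-representation targets; no geodesic area computation; no
geometry repair or projection handling (ranges and reserves arrive as
masks/records); greedy solutions carry no optimality certificate; and the
species-target dip documented above is reproduced faithfully rather than
patched.
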
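# landprior

Joint spatial prioritization of **nature's contributions to people (NCP)**
and terrestrial vertebrate biodiversity, as a tested, desk-scale analysis
pipeline driven by a synthetic-landscape generator.

Global conservation planning increasingly asks a single question in two
currencies: which places, if conserved or sustainably managed, would keep
most of the ecosystem services people rely on (carbon retention, flood
regulation, pollination, timber, access to nature, ...) *and* meet minimum
habitat-representation targets for thousands of vertebrate species — and
how badly do those places collide with land wanted by agriculture, energy,
mining and cities?  The real analyses behind that question run on
restricted-access global rasters (IUCN ranges, WDPA, published development
suitability layers).  This package reimplements the entire analytical
chain on seeded synthetic landscapes with the same statistical structure,
so every stage is reproducible, testable and inspectable on a laptop.

## The model

Prioritization is the **minimum set** reserve-selection problem.  With
planning units *i ∈ I* (equal-area grid cells, cost *cᵢ* = cell area in
km²), features *j ∈ J* (ten NCP layers plus one Area-of-Habitat per
species, amounts *rᵢⱼ*), and representation targets *Tⱼ*:

```
minimize   Σᵢ xᵢ cᵢ
subject to Σᵢ xᵢ rᵢⱼ ≥ Tⱼ   for all j ∈ J,   xᵢ ∈ {0, 1}
```

NCP targets are a fraction (5–95%) of each layer's total; species targets
follow a habitat-area rule — 100% of AOH below 1,000 km², 10% above
250,000 km², a log-linear fraction in between, capped at 1,000,000 km².
Protected areas can be locked into the solution.  Around the optimization
sit the supporting stages: AOH construction (range ∩ suitable landcover ∩
elevational band, with majority-rule aggregation between resolutions),
protected-area register filtering (drop proposed/unknown and UNESCO
biosphere records, turn point records into discs of equal area),
per-country z-score classification of 0–1 development-suitability layers
into six percentile categories (high pressure = categories 5–6 of the
cellwise max over 14 sectors), and cell-count overlay reporting.

## Worked example

```bash
cd analysis
python 01_simulate_landscape.py
python 02_build_aoh_and_targets.py
python 03_prioritize_sweep.py
```

prints (seed 2024, 40×40 grid of 10 km cells):

```
landscape seed 2024: 40x40 cells, 70.2% natural or semi-natural, 31 species records (2 seasonal), 30 PA records -> results/landscape
31 AOH built (0 empty after refinement); median AOH 1600 km2; target branches: {'interp': 17, 'full': 14} -> results/aoh_targets
ncp_species: 19/19 levels proven optimal; land at 90% NCP = 58.6%
ncp_species_pa_locked: 19/19 levels proven optimal; land at 90% NCP = 61.8%
ncp_only: 17/19 levels proven optimal; land at 90% NCP = 58.4%
at 90% NCP: species adds 0.2 points of land; PA lock-in adds 3.2 points -> results/prioritization
```

Reading this: providing 90% of all ten NCP on this landscape needs 58.4%
of the land; adding all thirty species' representation targets costs only
0.2 further points (species priorities largely co-locate with NCP), while
forcing the existing protected-area estate into the solution costs 3.2
points, because reserves were not sited for NCP.  The `results/` tables
hold the full 19-level area curves, summed priority maps (which cells are
needed even at low targets), the development-pressure classification
(`04_development_pressure.py`) and the protection/pressure overlay report
(`05_overlay_report.py`).  All magnitudes are properties of the synthetic
landscape, not of the Earth; the pipeline's contracts (monotone area
curves, lock-in and species dominance, partitioned overlays) are what
carry over.

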
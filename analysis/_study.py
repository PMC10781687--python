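"""Shared study conditions for the numbered analysis drivers.

One seeded 40x40 landscape (10 km cells) with ten NCP layers, thirty
terrestrial vertebrate species, five countries, four biomes and fourteen
development sectors.  Every driver regenerates it deterministically from
the seed, so the scripts can be run independently and in any order.
"""

from pathlib import Path

from landprior import GridSpec, LandscapeParams, generate_landscape
from landprior.optimizer import SolveOptions

SEED = 2024
RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_PARAMS = LandscapeParams(
    grid=GridSpec(40, 40, 10.0),
    n_ncp=10,
    n_species=30,
    n_countries=5,
    n_biomes=4,
    seed=SEED,
)

# per-solve wall cap: rare equal-cost instances stall on a one-cell bound
# plateau; capped levels return their incumbent flagged feasible_gap
SOLVE_OPTIONS = SolveOptions(time_limit_s=60.0)


def study_landscape():
    return generate_landscape(STUDY_PARAMS)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
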
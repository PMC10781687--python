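"""Shared fixtures: tiny hand-built problems and a small seeded landscape."""

from __future__ import annotations

import numpy as np
import pytest

from landprior import (
    FeatureTable,
    GridSpec,
    LandscapeParams,
    PlanningUnits,
    ProblemInstance,
    generate_landscape,
)


def make_problem(costs, amounts, targets, locked_in=(), locked_out=(),
                 cell_side_km=1.0):
    """Build a 1 x n problem from plain dicts.

    ``amounts`` maps feature_id -> {unit_id: r_ij}; unit ids are column
    indices on a 1-row grid.
    """
    n = len(costs)
    grid = GridSpec(1, n, cell_side_km)
    units = PlanningUnits(grid, np.ones((1, n), dtype=bool),
                          cost=np.asarray(costs, dtype=float).reshape(1, n))
    ft = FeatureTable()
    for fid, amt in amounts.items():
        ids = np.array(sorted(amt), dtype=int)
        ft.add_feature(fid, "ncp", ids,
                       np.array([amt[u] for u in ids], dtype=float))
    return ProblemInstance(units, ft, dict(targets),
                           frozenset(locked_in), frozenset(locked_out))


@pytest.fixture
def three_unit_problem():
    """Unit u3 alone covers both features; u1/u2 cover one each."""
    return make_problem(
        costs=[1.0, 1.0, 1.0],
        amounts={"f1": {0: 1.0, 2: 1.0}, "f2": {1: 1.0, 2: 1.0}},
        targets={"f1": 1.0, "f2": 1.0})


@pytest.fixture(scope="session")
def small_landscape():
    """A 20x20 landscape with 12 species; shared across read-only tests."""
    params = LandscapeParams(grid=GridSpec(20, 20, 10.0), n_species=12,
                             n_countries=3, n_biomes=2, seed=7)
    return generate_landscape(params)


def random_instance(rng, max_units=18, max_features=6):
    """A random feasible-by-construction minimum-set instance with
    integer costs (so objective sums are exact across backends)."""
    n = int(rng.integers(4, max_units + 1))
    m = int(rng.integers(1, max_features + 1))
    costs = rng.integers(1, 10, n).astype(float)
    amounts = {}
    targets = {}
    for j in range(m):
        fid = f"f{j}"
        k = int(rng.integers(1, n + 1))
        ids = rng.choice(n, k, replace=False)
        vals = rng.integers(1, 8, k).astype(float)
        amounts[fid] = {int(u): float(v) for u, v in zip(ids, vals)}
        total = float(vals.sum())
        targets[fid] = float(np.floor(rng.uniform(0.2, 0.9) * total))
    locked_in = ()
    if rng.random() < 0.3:
        locked_in = (int(rng.integers(n)),)
    return make_problem(costs, amounts, targets, locked_in=locked_in)
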
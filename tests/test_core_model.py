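import numpy as np
import pytest

from landprior import (
    GridSpec,
    Layer,
    PlanningUnits,
    Solution,
    assemble_problem,
    feasibility_check,
    verify_solution,
)
from landprior.optimizer import solve_exact

from conftest import make_problem


@pytest.fixture
def four_by_four():
    grid = GridSpec(4, 4, 10.0)
    units = PlanningUnits(grid, np.ones(grid.shape, dtype=bool))
    ncp_a = Layer(grid, np.arange(16, dtype=float).reshape(4, 4), name="a")
    ncp_b = Layer(grid, np.ones((4, 4)), name="b")
    aoh = np.zeros((4, 4))
    aoh[0, :3] = 1  # three habitat cells of 100 km2 each
    sp = Layer(grid, aoh, name="sp1")
    return grid, units, [ncp_a, ncp_b], [sp]


def test_assemble_counts_features_and_units(four_by_four):
    grid, units, ncp, species = four_by_four
    prob = assemble_problem(ncp, species, units,
                            {"a": 0.0, "b": 0.0, "sp1": 0.0})
    assert prob.n_features == 3
    assert prob.n_units == 16
    # species amounts are cell areas on habitat cells
    assert prob.features.total_available("sp1") == pytest.approx(300.0)
    assert prob.features.kind["sp1"] == "species"


def test_assemble_is_deterministic(four_by_four):
    grid, units, ncp, species = four_by_four
    t = {"a": 0.0, "b": 0.0, "sp1": 0.0}
    p1 = assemble_problem(ncp, species, units, t)
    p2 = assemble_problem(ncp, species, units, t)
    assert p1.features.to_frame().equals(p2.features.to_frame())


def test_assemble_rejects_grid_mismatch_and_negatives(four_by_four):
    grid, units, ncp, species = four_by_four
    other = Layer(GridSpec(3, 3, 10.0), np.ones((3, 3)), name="a")
    with pytest.raises(ValueError):
        assemble_problem([other], species, units, {"a": 0, "sp1": 0})
    neg = Layer(grid, -np.ones((4, 4)), name="a")
    with pytest.raises(ValueError):
        assemble_problem([neg], species, units, {"a": 0, "sp1": 0})
    with pytest.raises(KeyError):
        assemble_problem(ncp, species, units,
                         {"a": 0, "b": 0, "sp1": 0, "ghost": 1})


def test_zero_layer_with_zero_target_is_satisfiable():
    prob = make_problem([1.0, 1.0], {"z": {}}, {"z": 0.0})
    assert feasibility_check(prob) == []
    sol = solve_exact(prob)
    assert sol.selected == frozenset()
    assert sol.objective_km2 == 0.0


def test_feasibility_check_reports_deficits():
    prob = make_problem([1.0, 1.0], {"f": {0: 2.0, 1: 3.0}}, {"f": 10.0})
    assert feasibility_check(prob) == [("f", 5.0)]
    ok = make_problem([1.0, 1.0], {"f": {0: 2.0, 1: 3.0}}, {"f": 5.0})
    assert feasibility_check(ok) == []


def test_feasibility_check_accounts_for_locked_out():
    # locking out the only cell holding a full-target species
    prob = make_problem([1.0, 1.0], {"sp": {0: 100.0}}, {"sp": 100.0},
                        locked_out=(0,))
    # independent recomputation: total excluding locked_out is 0
    assert feasibility_check(prob) == [("sp", 100.0)]


def test_verify_solution_cases(three_unit_problem):
    prob = make_problem([1.0], {"f": {}}, {"f": 0.0})
    empty = Solution(frozenset(), 0.0, {"f": 0.0}, "optimal", "exact")
    ok, viol = verify_solution(prob, empty)
    assert ok and viol == []

    all_sel = Solution(frozenset({0, 1, 2}), 3.0,
                       {"f1": 2.0, "f2": 2.0}, "optimal", "exact")
    ok, _ = verify_solution(three_unit_problem, all_sel)
    assert ok

    locked = make_problem([1.0, 1.0], {"f": {0: 1.0, 1: 1.0}}, {"f": 1.0},
                          locked_in=(0,))
    missing = Solution(frozenset({1}), 1.0, {"f": 1.0}, "optimal", "exact")
    ok, viol = verify_solution(locked, missing)
    assert not ok and any("locked_in" in v for v in viol)


def test_solution_bookkeeping_matches_brute_recount(three_unit_problem):
    sol = solve_exact(three_unit_problem)
    # attainment by direct summation over the sparse amounts
    for fid in three_unit_problem.features.feature_ids:
        amt = three_unit_problem.features.amounts(fid)
        brute = sum(a for u, a in amt.items() if u in sol.selected)
        assert sol.attainment[fid] == pytest.approx(brute, rel=1e-9)
    # objective equals cell count x cell area on equal-area grids
    grid = GridSpec(3, 3, 10.0)
    units = PlanningUnits(grid, np.ones(grid.shape, dtype=bool))
    lyr = Layer(grid, np.ones(grid.shape), name="n")
    prob = assemble_problem([lyr], [], units, {"n": 5.0})
    s = solve_exact(prob)
    assert s.objective_km2 == pytest.approx(
        len(s.selected) * grid.cell_area_km2)


def test_feature_table_csv_roundtrip(tmp_path, four_by_four):
    grid, units, ncp, species = four_by_four
    prob = assemble_problem(ncp, species, units,
                            {"a": 0.0, "b": 0.0, "sp1": 0.0})
    path = tmp_path / "amounts.csv"
    prob.features.to_csv(path)
    from landprior import FeatureTable
    back = FeatureTable.from_csv(path, prob.features.kind)
    assert back.to_frame().equals(prob.features.to_frame())
    assert back.totals() == prob.features.totals()


def test_lp_text_listing(three_unit_problem):
    text = three_unit_problem.to_lp_text()
    assert "minimize" in text and ">= 1" in text and "binary" in text
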
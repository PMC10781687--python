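"""Minimum-set solvers: exact (mixed-integer programming via HiGHS),
greedy (fast fallback), and brute-force enumeration (test oracle).

The problem is the classic reserve-selection minimum set: minimize
``sum_i x_i c_i`` subject to ``sum_i x_i r_ij >= T_j`` for all features j,
with binary x_i, locked-in units forced to 1 and locked-out to 0.
The default relative gap is 0 (prove optimality): desk-scale instances are
small and tests must not depend on near-optimal slack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .core_model import ProblemInstance, Solution, feasibility_check

_BRUTE_FORCE_LIMIT = 20


@dataclass(frozen=True)
class SolveOptions:
    backend: str = "exact"  # exact | greedy | brute_force
    relative_gap: float = 0.0
    time_limit_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_gap < 1.0:
            raise ValueError("relative_gap must lie in [0, 1)")
        if self.backend not in ("exact", "greedy", "brute_force"):
            raise ValueError(f"unknown backend {self.backend!r}")


def _make_solution(problem: ProblemInstance, selected: frozenset[int],
                   status: str, backend: str, gap: float = 0.0) -> Solution:
    sel_sorted = sorted(selected)
    return Solution(
        selected=frozenset(selected),
        objective_km2=problem.units.cost_of(sel_sorted),
        attainment={f: problem.features.attainment(f, sel_sorted)
                    for f in problem.features.feature_ids},
        status=status, backend=backend, gap=gap)


def _infeasible(problem: ProblemInstance, backend: str) -> Solution:
    # report the locked-in baseline so violating features are inspectable
    return _make_solution(problem, frozenset(problem.locked_in),
                          "infeasible", backend)


def solve_exact(problem: ProblemInstance,
                options: SolveOptions = SolveOptions()) -> Solution:
    """Solve to proven optimality (or to ``relative_gap``) with HiGHS."""
    if feasibility_check(problem):
        return _infeasible(problem, "exact")
    ids = problem.units.ids
    n = ids.size
    pos = {int(u): k for k, u in enumerate(ids)}
    c = problem.units.cost.reshape(-1)[ids].astype(float)

    lb = np.zeros(n)
    ub = np.ones(n)
    for u in problem.locked_in:
        lb[pos[u]] = 1.0
    for u in problem.locked_out:
        ub[pos[u]] = 0.0

    rows, cols, data, tgt = [], [], [], []
    j = 0
    for fid in problem.features.feature_ids:
        t = problem.targets[fid]
        if t <= 0:
            continue
        for u, a in problem.features.amounts(fid).items():
            rows.append(j)
            cols.append(pos[u])
            data.append(a)
        tgt.append(t)
        j += 1

    constraints = []
    if j:
        A = csr_matrix((data, (rows, cols)), shape=(j, n))
        constraints.append(LinearConstraint(A, lb=np.asarray(tgt),
                                            ub=np.inf))

    milp_opts: dict = {"mip_rel_gap": options.relative_gap}
    if options.time_limit_s is not None:
        milp_opts["time_limit"] = options.time_limit_s
    # On equal-cost (minimum-area) instances the objective is integral in
    # units of one cell cost, so an absolute gap below that unit still
    # proves the optimal objective value while skipping the symmetric
    # branch-and-bound tail that plagues minimum-set problems.
    if options.relative_gap == 0 and n and np.ptp(c) == 0 and c[0] > 0:
        milp_opts["mip_abs_gap"] = 0.999 * c[0]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Unrecognized options",
                                category=RuntimeWarning)
        res = milp(c, constraints=constraints, integrality=np.ones(n),
                   bounds=Bounds(lb, ub), options=milp_opts)

    if res.status == 2:
        return _infeasible(problem, "exact")
    if res.x is None:
        raise RuntimeError(
            "solver stopped before finding any feasible selection; "
            "raise time_limit_s")
    x = res.x > 0.5
    selected = frozenset(int(u) for u in ids[x])
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    if res.status == 0 and "mip_abs_gap" in milp_opts:
        # terminated under the integral-objective criterion: the objective
        # value is provably optimal even though the relative gap is not 0
        status, gap = "optimal", 0.0
    elif res.status == 0 and gap <= max(options.relative_gap, 1e-9):
        status = "optimal"
    else:
        status = "feasible_gap"
    return _make_solution(problem, selected, status, "exact", gap=gap)


def solve_greedy(problem: ProblemInstance,
                 options: SolveOptions = SolveOptions(backend="greedy")
                 ) -> Solution:
    """Cost-effectiveness greedy: repeatedly add the unit maximizing
    ``sum_j min(r_ij, remaining_deficit_j) / c_i``; ties break to the
    lowest unit id.  Feasible whenever the problem is; objective >= exact.
    """
    if feasibility_check(problem):
        return _infeasible(problem, "greedy")
    cost_flat = problem.units.cost.reshape(-1)
    selected: set[int] = set(problem.locked_in)
    deficits = {f: problem.targets[f]
                - problem.features.attainment(f, selected)
                for f in problem.features.feature_ids}
    # per-unit feature amounts for the scoring loop
    unit_amounts: dict[int, list[tuple[str, float]]] = {}
    for fid in problem.features.feature_ids:
        for u, a in problem.features.amounts(fid).items():
            unit_amounts.setdefault(u, []).append((fid, a))

    candidates = set(problem.free_unit_ids().tolist())
    while any(d > 1e-9 for d in deficits.values()):
        best_u, best_score = -1, 0.0
        for u in sorted(candidates):
            score = 0.0
            for fid, a in unit_amounts.get(u, ()):  # zero rows score 0
                d = deficits[fid]
                if d > 1e-9:
                    score += min(a, d)
            score /= cost_flat[u]
            if score > best_score + 1e-12:
                best_u, best_score = u, score
        if best_u < 0:
            return _infeasible(problem, "greedy")
        selected.add(best_u)
        candidates.discard(best_u)
        for fid, a in unit_amounts.get(best_u, ()):
            deficits[fid] -= a
    # greedy is feasible but carries no optimality proof; gap is not
    # computed (reported as 0 by convention, status stays feasible_gap)
    return _make_solution(problem, frozenset(selected), "feasible_gap",
                          "greedy")


def solve_brute_force(problem: ProblemInstance,
                      options: SolveOptions = SolveOptions(
                          backend="brute_force")) -> Solution:
    """Exhaustive enumeration over free units (test oracle).

    Returns a minimum-cost feasible subset containing all locked-in and no
    locked-out units; ties break to the lexicographically smallest sorted
    selection.  Refuses instances with more than 20 free units.
    """
    free = sorted(problem.free_unit_ids().tolist())
    n = len(free)
    if n > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"{n} free units exceed the brute-force limit "
            f"({_BRUTE_FORCE_LIMIT})")
    locked = sorted(problem.locked_in)
    fids = problem.features.feature_ids
    cost_flat = problem.units.cost.reshape(-1)

    # dense amounts over free units; locked-in contributions are constant
    A = np.zeros((len(fids), n))
    resid = np.empty(len(fids))
    for j, fid in enumerate(fids):
        amt = problem.features.amounts(fid)
        for k, u in enumerate(free):
            A[j, k] = amt.get(u, 0.0)
        resid[j] = problem.targets[fid] \
            - problem.features.attainment(fid, locked)

    # enumerate all 2^n subsets as a bit matrix
    masks = np.arange(1 << n, dtype=np.uint32)
    X = ((masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1
         ).astype(np.float64)
    feasible = np.all(X @ A.T >= resid - 1e-9, axis=1)
    if not feasible.any():
        return _infeasible(problem, "brute_force")
    costs = X @ cost_flat[free]
    fcosts = np.where(feasible, costs, np.inf)
    best_cost = fcosts.min()
    # lexicographically smallest sorted selection among cost ties
    tie_idx = np.flatnonzero(fcosts <= best_cost + 1e-9)
    best_sel: tuple[int, ...] | None = None
    for m in tie_idx:
        sel = tuple(sorted(locked + [free[k] for k in range(n)
                                     if (int(m) >> k) & 1]))
        if best_sel is None or sel < best_sel:
            best_sel = sel
    return _make_solution(problem, frozenset(best_sel), "optimal",
                          "brute_force")


def solve(problem: ProblemInstance,
          options: SolveOptions = SolveOptions()) -> Solution:
    """Dispatch to the backend named in ``options``."""
    if options.backend == "exact":
        return solve_exact(problem, options)
    if options.backend == "greedy":
        return solve_greedy(problem, options)
    return solve_brute_force(problem, options)
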
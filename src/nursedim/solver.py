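"""Exact minimization of a staffing instance.

The search is a depth-first branch-and-bound over the integer lattice of
staff counts.  Night parity is substituted out first (one variable per skill
covers both night cohorts), leaving six bounded integer variables:
(skill x {morning, afternoon, night}).  Variables are branched in order of
increasing salary cost per optimistically delivered care hour, so cheap
coverage is explored first; a node's lower bound is its committed salary
plus the cheapest conceivable completion of the residual demand.  Morning/
afternoon balance and minimum cover restrict branch ranges directly, and a
skill-mix bound prunes branches that can no longer reach the required nurse
fraction.

``solve_oracle`` is a deliberately naive exhaustive enumeration over the
same lattice, used to verify the branch-and-bound on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import (
    CELLS,
    AggShift,
    ModelParameters,
    ModelVariant,
    Shift,
    Skill,
    StaffingInstance,
    StaffingSolution,
    best_aux_levels,
    build_instance,
    check_feasibility,
    max_delivered_hours,
)

__all__ = [
    "solve",
    "solve_oracle",
    "InfeasibleInstanceError",
    "OracleCapExceeded",
    "random_instance",
    "random_instances",
    "DEFAULT_PROPERTY_SEED",
]

_EPS = 1e-6
_COST_TOL = 1e-9

DEFAULT_PROPERTY_SEED = 20160907
DEFAULT_ORACLE_CAP = 8


class InfeasibleInstanceError(Exception):
    """No staffing within the variable bounds satisfies every constraint.

    ``families`` names the constraint families still violated by the most
    generous staffing the bounds allow — the binding obstruction.
    """

    def __init__(self, families: Sequence[str]):
        self.families = tuple(families)
        super().__init__(
            "staffing instance is infeasible within variable bounds; "
            f"binding constraint families: {', '.join(self.families) or '?'}")


class OracleCapExceeded(ValueError):
    """Instance too large for exhaustive enumeration (oracle is test-only)."""


@dataclass(frozen=True)
class _Cell:
    """One reduced search variable: a (skill, slot) head count.

    For the night slot the count is per cohort; costs and worker tallies
    account for both cohorts.
    """

    skill: Skill
    slot: AggShift
    cost: float          # salary per unit count
    delivery: float      # optimistic care hours per unit count
    workers: float       # employees per unit count (2 for night)
    prop_workers: float  # employees counted by the skill-mix rule
    lb: int
    ub: int


def _reduced_cells(instance: StaffingInstance) -> list[_Cell]:
    costs, shifts, variant = instance.costs, instance.shifts, instance.variant
    buffer = 1.0 + instance.tsi
    cells = []
    for skill in Skill:
        if variant.tsi_scope == "per_cell":
            ratios = None
        else:
            # Pooled TSI budget: a unit of any cell feeds the best use.
            options = []
            pool = [skill] if variant.tsi_scope == "per_skill" else list(Skill)
            for i in pool:
                night = shifts.length(i, Shift.NIGHT1)
                gn = (2.0 * night if variant.night_demand_hours
                      == "both_cohorts" else night)
                options += [shifts.length(i, Shift.MORNING),
                            shifts.length(i, Shift.AFTERNOON), gn / 2.0]
            ratios = max(options)
        for slot in AggShift:
            if slot is AggShift.NIGHT:
                s1, s2 = Shift.NIGHT1, Shift.NIGHT2
                cost = (costs.worker_cost(skill, s1, shifts)
                        + costs.worker_cost(skill, s2, shifts))
                night = shifts.length(skill, s1)
                if variant.tsi_scope == "per_cell":
                    if variant.night_demand_hours == "both_cohorts":
                        delivery = 2.0 * night / buffer
                    else:
                        delivery = night / buffer
                else:
                    delivery = 2.0 * ratios / buffer
                workers = 2.0
                prop_workers = (2.0 if variant.prop_counting
                                == "all_employees" else 1.0)
                lb = max(instance.min_staff[(skill, s1)],
                         instance.min_staff[(skill, s2)])
                ub = min(instance.upper_bounds[(skill, s1)],
                         instance.upper_bounds[(skill, s2)])
            else:
                s = (Shift.MORNING if slot is AggShift.MORNING
                     else Shift.AFTERNOON)
                cost = costs.worker_cost(skill, s, shifts)
                if variant.tsi_scope == "per_cell":
                    delivery = shifts.length(skill, s) / buffer
                else:
                    delivery = ratios / buffer
                workers = 1.0
                prop_workers = 1.0
                lb = instance.min_staff[(skill, s)]
                ub = instance.upper_bounds[(skill, s)]
            cells.append(_Cell(skill, slot, cost, delivery, workers,
                               prop_workers, int(lb), int(ub)))
    return cells


def _expand(cells: Sequence[_Cell], values: Sequence[int]
            ) -> dict[tuple[Skill, Shift], int]:
    x: dict[tuple[Skill, Shift], int] = {}
    for cell, v in zip(cells, values):
        if cell.slot is AggShift.NIGHT:
            x[(cell.skill, Shift.NIGHT1)] = v
            x[(cell.skill, Shift.NIGHT2)] = v
        elif cell.slot is AggShift.MORNING:
            x[(cell.skill, Shift.MORNING)] = v
        else:
            x[(cell.skill, Shift.AFTERNOON)] = v
    return x


def _solution_key(instance: StaffingInstance,
                  x: dict[tuple[Skill, Shift], int], cost: float):
    nurse_vec = tuple(x[(Skill.NURSE, s)] for s in Shift)
    tech_vec = tuple(x[(Skill.TECHNICIAN, s)] for s in Shift)
    total = sum(nurse_vec) + sum(tech_vec)
    return (round(cost, 9), total, nurse_vec, tech_vec)


def _finalize(instance: StaffingInstance,
              x: dict[tuple[Skill, Shift], int],
              cost: float) -> StaffingSolution:
    y = (best_aux_levels(x, instance)
         if instance.variant.tsi_scope == "per_cell" else None)
    return StaffingSolution(x=dict(x), y=y, objective_cost=float(cost))


def _infeasibility_families(instance: StaffingInstance) -> list[str]:
    """Constraint families violated even by the most generous staffing."""
    generous = {cell: int(instance.upper_bounds[cell]) for cell in CELLS}
    # Respect structural constraints so only genuine obstructions remain.
    for i in Skill:
        n = min(generous[(i, Shift.NIGHT1)], generous[(i, Shift.NIGHT2)])
        generous[(i, Shift.NIGHT1)] = generous[(i, Shift.NIGHT2)] = n
    violations = check_feasibility(StaffingSolution(x=generous), instance)
    families = sorted({v.family for v in violations})
    return families or ["bounds"]


def solve(instance: StaffingInstance) -> StaffingSolution:
    """Minimum-salary feasible staffing, deterministic.

    Among equally cheap staffings the solution with the lexicographically
    smallest (total staff, nurse vector, technician vector) is returned.
    Raises :class:`InfeasibleInstanceError` when the bounds admit no
    feasible staffing.
    """
    cells = _reduced_cells(instance)
    order = sorted(range(6), key=lambda j: (cells[j].cost
                                            / max(cells[j].delivery, _EPS),
                                            j))
    cells = [cells[j] for j in order]
    for cell in cells:
        if cell.lb > cell.ub:
            raise InfeasibleInstanceError(["min_cover"])
    H = instance.demand_hours
    prop = instance.prop
    n = len(cells)

    # Suffix aggregates for bounding (index j means cells[j:]).
    suf_min_cost = [0.0] * (n + 1)
    suf_min_deliv = [0.0] * (n + 1)
    suf_max_deliv = [0.0] * (n + 1)
    suf_best_rate = [math.inf] * (n + 1)
    suf_prop_max = [0.0] * (n + 1)
    prop_coef = []
    for cell in cells:
        if cell.skill is Skill.NURSE:
            prop_coef.append((1.0 - prop) * cell.prop_workers)
        else:
            prop_coef.append(-prop * cell.prop_workers)
    for j in range(n - 1, -1, -1):
        c = cells[j]
        suf_min_cost[j] = suf_min_cost[j + 1] + c.lb * c.cost
        suf_min_deliv[j] = suf_min_deliv[j + 1] + c.lb * c.delivery
        suf_max_deliv[j] = suf_max_deliv[j + 1] + c.ub * c.delivery
        suf_best_rate[j] = min(suf_best_rate[j + 1],
                               c.cost / max(c.delivery, _EPS))
        bound_val = c.ub if prop_coef[j] > 0 else c.lb
        suf_prop_max[j] = suf_prop_max[j + 1] + prop_coef[j] * bound_val

    partner = {}  # index of the already-branched M/A partner, if any
    seen: dict[tuple[Skill, AggShift], int] = {}
    for j, c in enumerate(cells):
        if c.slot in (AggShift.MORNING, AggShift.AFTERNOON):
            other = (AggShift.AFTERNOON if c.slot is AggShift.MORNING
                     else AggShift.MORNING)
            if (c.skill, other) in seen:
                partner[j] = seen[(c.skill, other)]
            seen[(c.skill, c.slot)] = j

    best_key = None
    best_x = None
    values = [0] * n

    def dfs(j: int, cost_so_far: float, deliv_so_far: float,
            prop_so_far: float) -> None:
        nonlocal best_key, best_x
        if j == n:
            x = _expand(cells, values)
            delivered = max_delivered_hours(x, instance)
            if delivered < H - _EPS:
                return
            if prop_so_far < -_EPS:
                return
            key = _solution_key(instance, x, cost_so_far)
            if best_key is None or key < best_key:
                best_key, best_x = key, x
            return
        cell = cells[j]
        lo, hi = cell.lb, cell.ub
        if j in partner:
            alpha = int(instance.alpha[cell.skill])
            pv = values[partner[j]]
            lo = max(lo, pv - alpha)
            hi = min(hi, pv + alpha)
        if cell.delivery > 0:
            need = H - deliv_so_far - suf_max_deliv[j + 1] - _EPS
            if need > 0:
                lo = max(lo, math.ceil(need / cell.delivery))
        for v in range(lo, hi + 1):
            values[j] = v
            cost = cost_so_far + v * cell.cost
            deliv = deliv_so_far + v * cell.delivery
            prop_acc = prop_so_far + v * prop_coef[j]
            residual = H - deliv - suf_min_deliv[j + 1]
            bound = cost + suf_min_cost[j + 1]
            if residual > _EPS:
                bound += residual * suf_best_rate[j + 1]
            if best_key is not None and bound > best_key[0] + _COST_TOL:
                if residual <= _EPS:
                    break  # larger v only raises the bound
                continue
            if prop_acc + suf_prop_max[j + 1] < -_EPS:
                if prop_coef[j] < 0:
                    break  # more of this skill only hurts the nurse ratio
                continue
            dfs(j + 1, cost, deliv, prop_acc)

    dfs(0, 0.0, 0.0, 0.0)
    if best_x is None:
        raise InfeasibleInstanceError(_infeasibility_families(instance))
    return _finalize(instance, best_x, best_key[0])


def solve_oracle(instance: StaffingInstance,
                 cap: int = DEFAULT_ORACLE_CAP) -> StaffingSolution:
    """Exhaustive-enumeration optimum, for verification only.

    Enumerates every integer staffing within the instance bounds (night
    parity built in), keeps the feasible one with the smallest
    (cost, total staff, nurse vector, technician vector).  Refuses
    instances whose bounds exceed ``cap`` — the oracle exists to check
    :func:`solve` on small instances, not to replace it.
    """
    cells = _reduced_cells(instance)
    for cell in cells:
        if cell.ub > cap:
            raise OracleCapExceeded(
                f"upper bound {cell.ub} exceeds oracle cap {cap}")
    H = instance.demand_hours
    best_key = None
    best_x = None
    ranges = [range(c.lb, c.ub + 1) for c in cells]
    alphas = {i: int(instance.alpha[i]) for i in Skill}
    slots = [(c.skill, c.slot) for c in cells]
    idx = {pair: k for k, pair in enumerate(slots)}
    for values in itertools.product(*ranges):
        ok = True
        for i in Skill:
            gap = abs(values[idx[(i, AggShift.MORNING)]]
                      - values[idx[(i, AggShift.AFTERNOON)]])
            if gap > alphas[i]:
                ok = False
                break
        if not ok:
            continue
        cost = sum(v * c.cost for v, c in zip(values, cells))
        if best_key is not None and cost > best_key[0] + _COST_TOL:
            continue
        x = _expand(cells, values)
        if max_delivered_hours(x, instance) < H - _EPS:
            continue
        nurses = sum(v * c.prop_workers for v, c in zip(values, cells)
                     if c.skill is Skill.NURSE)
        total = sum(v * c.prop_workers for v, c in zip(values, cells))
        if nurses < instance.prop * total - _EPS:
            continue
        key = _solution_key(instance, x, cost)
        if best_key is None or key < best_key:
            best_key, best_x = key, x
    if best_x is None:
        raise InfeasibleInstanceError(_infeasibility_families(instance))
    return _finalize(instance, best_x, best_key[0])


# ---------------------------------------------------------------------------
# Seeded random instances for property-based verification
# ---------------------------------------------------------------------------

def random_instance(rng: np.random.Generator,
                    variant: ModelVariant | None = None,
                    cap: int = 3) -> StaffingInstance:
    """One random small staffing instance.

    Demand, buffer, nurse fraction, balance bounds and minimum cover are
    drawn from ranges small enough that the enumeration oracle stays cheap;
    variable upper bounds are clipped at ``cap`` per cell.  Instances may
    be infeasible by construction — callers exercise that path too.
    """
    demand = float(rng.uniform(0.0, 60.0))
    tsi = float(rng.choice([0.0, 0.15, 0.3]))
    prop = float(rng.uniform(0.0, 0.6))
    alpha = {i: int(rng.integers(0, 4)) for i in Skill}
    min_staff = {cell: int(rng.integers(0, 2)) for cell in CELLS}
    # Night cohorts share a minimum so parity cannot clash with cover.
    for i in Skill:
        m = max(min_staff[(i, Shift.NIGHT1)], min_staff[(i, Shift.NIGHT2)])
        min_staff[(i, Shift.NIGHT1)] = min_staff[(i, Shift.NIGHT2)] = m
    params = ModelParameters(tsi=tsi, prop=prop, alpha=alpha,
                             min_staff=min_staff)
    return build_instance(demand, params, variant=variant or ModelVariant(),
                          upper_bound_cap=cap)


def random_instances(n: int, seed: int = DEFAULT_PROPERTY_SEED,
                     variant: ModelVariant | None = None,
                     cap: int = 3) -> Iterator[StaffingInstance]:
    """Reproducible stream of ``n`` random small instances."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield random_instance(rng, variant=variant, cap=cap)
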
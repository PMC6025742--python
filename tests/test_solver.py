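"""Branch-and-bound solver vs the enumeration oracle and an external MILP."""

import numpy as np
import pytest

from nursedim import (
    ModelParameters,
    ModelVariant,
    Shift,
    Skill,
    StaffingInstance,
    build_instance,
    check_feasibility,
)
from nursedim.model import AggShift
from nursedim.solver import (
    InfeasibleInstanceError,
    OracleCapExceeded,
    random_instances,
    solve,
    solve_oracle,
)


def uniform(min_staff=0, **kwargs):
    return ModelParameters.with_uniform_min_staff(min_staff, **kwargs)


class TestSolveExamples:
    def test_small_unbuffered_demand(self):
        # 12 care hours, no buffer, no minima: two day technicians suffice.
        inst = build_instance(
            12.0, uniform(tsi=0.0, prop=0.0,
                          alpha={Skill.NURSE: 2, Skill.TECHNICIAN: 2}))
        out = solve(inst)
        assert out.objective_cost == pytest.approx(7.2)
        assert out.nurse_total == 0 and out.technician_total == 2
        assert solve_oracle(inst, cap=10).objective_cost \
            == pytest.approx(7.2)

    def test_minimum_cover_forces_the_floor(self):
        inst = build_instance(0.0, ModelParameters(tsi=0.15, prop=0.0))
        out = solve(inst)
        assert out.vector(Skill.NURSE) == (1, 1, 1, 1)
        assert out.vector(Skill.TECHNICIAN) == (1, 1, 1, 1)
        # 45 m.u. of nurse wages plus 60% of that for technicians.
        assert out.objective_cost == pytest.approx(72.0)

    def test_zero_instance_solves_to_zero(self):
        inst = build_instance(0.0, uniform(0, prop=0.0))
        assert solve(inst).objective_cost == 0.0
        assert solve_oracle(inst).objective_cost == 0.0

    def test_contradictory_instance_raises_typed_signal(self):
        # Nurse share of 90% cannot be met: technicians are forced in by
        # minimum cover while nurse counts are capped by tight bounds.
        params = ModelParameters(tsi=0.0, prop=0.9)
        inst = build_instance(0.0, params, upper_bound_cap=1)
        with pytest.raises(InfeasibleInstanceError) as err:
            solve(inst)
        assert "skill_mix" in err.value.families
        with pytest.raises(InfeasibleInstanceError):
            solve_oracle(inst)

    def test_full_scale_day_solves_and_verifies(self):
        inst = build_instance(164.0, ModelParameters(prop=0.35))
        out = solve(inst)
        assert check_feasibility(out, inst) == []
        assert out.nurse_total >= 0.35 * out.total_staff - 1e-9


class TestOracle:
    def test_cap_refusal(self):
        inst = build_instance(164.0, ModelParameters(prop=0.35))
        with pytest.raises(OracleCapExceeded):
            solve_oracle(inst, cap=8)

    @pytest.mark.parametrize("variant", [
        ModelVariant(tsi_scope=scope, aux_integrality=integ,
                     night_demand_hours=night, prop_counting=propc)
        for scope in ("per_cell", "per_skill", "global")
        for integ in ("continuous", "integer")
        for night in ("both_cohorts", "single_cohort")
        for propc in ("all_employees", "per_day_staff")
    ], ids=lambda v: f"{v.tsi_scope}-{v.aux_integrality}-"
                     f"{v.night_demand_hours}-{v.prop_counting}")
    def test_matches_oracle_under_every_variant(self, variant):
        for inst in random_instances(8, seed=99, variant=variant):
            try:
                a = solve(inst).objective_cost
            except InfeasibleInstanceError:
                a = None
            try:
                b = solve_oracle(inst).objective_cost
            except InfeasibleInstanceError:
                b = None
            assert (a is None) == (b is None)
            if a is not None:
                assert a == pytest.approx(b, abs=1e-6)

    def test_matches_solver_on_a_seeded_sample(self):
        for inst in random_instances(25, seed=4):
            try:
                a = solve(inst).objective_cost
            except InfeasibleInstanceError:
                a = None
            try:
                b = solve_oracle(inst).objective_cost
            except InfeasibleInstanceError:
                b = None
            assert (a is None) == (b is None)
            if a is not None:
                assert a == pytest.approx(b, abs=1e-6)


class TestSolutionProperties:
    def test_determinism_of_repeated_solves(self):
        inst = build_instance(120.6, ModelParameters(prop=0.34))
        first = solve(inst)
        for _ in range(3):
            again = solve(inst)
            assert again.x == first.x
            assert again.objective_cost == first.objective_cost

    def test_solutions_pass_the_feasibility_checker(self):
        for inst in random_instances(40, seed=11):
            try:
                out = solve(inst)
            except InfeasibleInstanceError:
                continue
            assert check_feasibility(out, inst) == []

    def test_night_parity_in_returned_solutions(self):
        for inst in random_instances(20, seed=7):
            try:
                out = solve(inst)
            except InfeasibleInstanceError:
                continue
            for i in Skill:
                assert out.x[(i, Shift.NIGHT1)] == out.x[(i, Shift.NIGHT2)]


def _milp_optimum(inst: StaffingInstance) -> float | None:
    """Independent optimum via scipy's MILP (default variant only).

    Variables: 6 integer staff counts (night parity substituted) plus 6
    continuous auxiliary levels.
    """
    from scipy.optimize import Bounds, LinearConstraint, milp

    reduced = [(i, u) for i in Skill for u in AggShift]
    shift_of = {AggShift.MORNING: Shift.MORNING,
                AggShift.AFTERNOON: Shift.AFTERNOON,
                AggShift.NIGHT: Shift.NIGHT1}
    nx = len(reduced)
    cost = np.zeros(2 * nx)
    lb = np.zeros(2 * nx)
    ub = np.full(2 * nx, np.inf)
    integrality = np.zeros(2 * nx)
    for k, (i, u) in enumerate(reduced):
        s = shift_of[u]
        mult = 2.0 if u is AggShift.NIGHT else 1.0
        cost[k] = mult * inst.costs.worker_cost(i, s, inst.shifts)
        if u is AggShift.NIGHT:
            lb[k] = max(inst.min_staff[(i, Shift.NIGHT1)],
                        inst.min_staff[(i, Shift.NIGHT2)])
            ub[k] = min(inst.upper_bounds[(i, Shift.NIGHT1)],
                        inst.upper_bounds[(i, Shift.NIGHT2)])
        else:
            lb[k] = inst.min_staff[(i, s)]
            ub[k] = inst.upper_bounds[(i, s)]
        integrality[k] = 1

    rows, lo, hi = [], [], []

    def add(coeffs, lower, upper):
        rows.append(coeffs)
        lo.append(lower)
        hi.append(upper)

    # Demand: both night cohorts' auxiliary hours count.
    demand = np.zeros(2 * nx)
    for k, (i, u) in enumerate(reduced):
        length = inst.shifts.length(i, shift_of[u])
        demand[nx + k] = 2.0 * length if u is AggShift.NIGHT else length
    add(demand, inst.demand_hours, np.inf)
    # Per-cell TSI link x >= (1+p) * y (night: 2z >= (1+p) * 2y).
    for k, (i, u) in enumerate(reduced):
        row = np.zeros(2 * nx)
        row[k] = 2.0 if u is AggShift.NIGHT else 1.0
        row[nx + k] = -(1.0 + inst.tsi) * (2.0 if u is AggShift.NIGHT
                                           else 1.0)
        add(row, 0.0, np.inf)
    # Skill mix over all employees.
    mix = np.zeros(2 * nx)
    for k, (i, u) in enumerate(reduced):
        workers = 2.0 if u is AggShift.NIGHT else 1.0
        mix[k] = workers * ((1.0 - inst.prop) if i is Skill.NURSE
                            else -inst.prop)
    add(mix, 0.0, np.inf)
    # Morning/afternoon balance.
    for i in Skill:
        row = np.zeros(2 * nx)
        row[reduced.index((i, AggShift.MORNING))] = 1.0
        row[reduced.index((i, AggShift.AFTERNOON))] = -1.0
        add(row, -float(inst.alpha[i]), float(inst.alpha[i]))

    res = milp(c=cost,
               constraints=LinearConstraint(np.array(rows), lo, hi),
               integrality=integrality, bounds=Bounds(lb, ub))
    if not res.success:
        return None
    return float(res.fun)


class TestMilpCrossCheck:
    """The hand-written search agrees with an off-the-shelf MILP solver."""

    def test_default_variant_objectives_match(self):
        checked = 0
        for inst in random_instances(30, seed=2024, cap=4):
            try:
                ours = solve(inst).objective_cost
            except InfeasibleInstanceError:
                ours = None
            other = _milp_optimum(inst)
            if ours is None:
                assert other is None
            else:
                assert other is not None
                assert ours == pytest.approx(other, abs=1e-6)
                checked += 1
        assert checked >= 10  # the sample must contain real problems

    def test_case_study_day_matches_milp(self):
        inst = build_instance(164.0, ModelParameters(prop=0.35))
        assert solve(inst).objective_cost == pytest.approx(
            _milp_optimum(inst), abs=1e-6)
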
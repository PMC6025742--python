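"""Phase II model: cost evaluation, feasibility checking, variants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nursedim import (
    CostSchedule,
    ModelParameters,
    ModelVariant,
    Shift,
    ShiftStructure,
    Skill,
    StaffingSolution,
    build_instance,
    check_feasibility,
    evaluate_cost,
    max_delivered_hours,
    required_nurse_count,
)

vec = st.tuples(*[st.integers(min_value=0, max_value=9)] * 4)


def solution(nurses, technicians):
    return StaffingSolution.from_vectors(nurses, technicians)


class TestEvaluateCost:
    @pytest.mark.parametrize("nurses, technicians, expected", [
        ((3, 4, 1, 1), (6, 6, 1, 1), 138.0),
        ((2, 3, 2, 2), (5, 5, 2, 2), 171.6),
        ((3, 3, 3, 3), (3, 3, 3, 3), 216.0),
        ((0, 0, 0, 0), (0, 0, 0, 0), 0.0),
    ])
    def test_known_salary_totals(self, nurses, technicians, expected):
        assert evaluate_cost(solution(nurses, technicians)) \
            == pytest.approx(expected)

    @given(a=vec, b=vec, c=vec, d=vec)
    def test_linearity(self, a, b, c, d):
        summed = solution([x + y for x, y in zip(a, c)],
                          [x + y for x, y in zip(b, d)])
        assert evaluate_cost(summed) == pytest.approx(
            evaluate_cost(solution(a, b)) + evaluate_cost(solution(c, d)))

    def test_both_night_cohorts_are_paid(self):
        one_cohort = solution((0, 0, 1, 0), (0, 0, 0, 0))
        both = solution((0, 0, 1, 1), (0, 0, 0, 0))
        assert evaluate_cost(both) == pytest.approx(
            2 * evaluate_cost(one_cohort))

    def test_default_cost_per_hour_ordering(self):
        costs, shifts = CostSchedule(), ShiftStructure()
        per_hour = [
            costs.hourly_rate(Skill.TECHNICIAN, Shift.MORNING),
            costs.hourly_rate(Skill.TECHNICIAN, Shift.NIGHT1),
            costs.hourly_rate(Skill.NURSE, Shift.MORNING),
            costs.hourly_rate(Skill.NURSE, Shift.NIGHT1),
        ]
        assert per_hour == pytest.approx([0.6, 0.825, 1.0, 1.375])
        assert sorted(per_hour) == per_hour


class TestRequiredNurseCount:
    @pytest.mark.parametrize("total, prop, expected", [
        (23, 0.35, 9),
        (0, 0.5, 0),
        (10, 0.0, 0),
        (20, 0.35, 7),  # exact product: 7.0 stays 7
    ])
    def test_smallest_count_meeting_ratio(self, total, prop, expected):
        assert required_nurse_count(total, prop) == expected

    def test_invalid_prop(self):
        with pytest.raises(ValueError):
            required_nurse_count(5, 1.0)


class TestBuildInstance:
    def test_zero_demand_zero_minimum_admits_empty_staffing(self):
        inst = build_instance(
            0.0, ModelParameters.with_uniform_min_staff(0, prop=0.0))
        empty = solution((0, 0, 0, 0), (0, 0, 0, 0))
        assert check_feasibility(empty, inst) == []

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            ModelParameters(alpha={Skill.NURSE: -1, Skill.TECHNICIAN: 1})

    def test_prop_at_least_one_rejected(self):
        with pytest.raises(ValueError, match="prop"):
            ModelParameters(prop=1.0)

    def test_upper_bounds_cover_single_cell_demand(self):
        inst = build_instance(113.2, ModelParameters(prop=0.34))
        # Even the least productive cell alone could cover the buffered
        # demand at its upper bound.
        for cell, ub in inst.upper_bounds.items():
            assert ub >= (1 + inst.tsi) * inst.demand_hours / 12.0


class TestCheckFeasibility:
    def test_all_zero_staffing_violates_demand_and_cover(self):
        inst = build_instance(100.0, ModelParameters(prop=0.0))
        families = {v.family for v in
                    check_feasibility(solution((0,) * 4, (0,) * 4), inst)}
        assert families == {"demand", "min_cover"}

    def test_balance_violation_detected(self):
        inst = build_instance(
            0.0, ModelParameters.with_uniform_min_staff(0, prop=0.0))
        violations = check_feasibility(solution((5, 1, 1, 1), (0,) * 4), inst)
        assert [v.name for v in violations] == ["balance[nurse]"]
        assert violations[0].slack == pytest.approx(3)  # |5-1| exceeds 1 by 3

    def test_night_parity_violation_detected(self):
        inst = build_instance(
            0.0, ModelParameters.with_uniform_min_staff(0, prop=0.0))
        names = [v.name for v in
                 check_feasibility(solution((1, 1, 2, 1), (0,) * 4), inst)]
        assert names == ["night_parity[nurse]"]

    def test_skill_mix_counts_all_employees_by_default(self):
        inst = build_instance(
            0.0, ModelParameters.with_uniform_min_staff(0, prop=0.5))
        # 4 nurses vs 4 technicians: exactly at the 50% bound.
        assert check_feasibility(solution((1, 1, 1, 1), (1, 1, 1, 1)),
                                 inst) == []
        under = check_feasibility(solution((1, 1, 0, 0), (1, 1, 1, 1)), inst)
        assert [v.family for v in under] == ["skill_mix"]

    def test_explicit_aux_levels_are_validated(self):
        inst = build_instance(
            10.0, ModelParameters.with_uniform_min_staff(0, prop=0.0))
        x = solution((0, 0, 0, 0), (2, 0, 0, 0)).x
        # Claimed pre-buffer level exceeds what 2 technicians can back.
        from nursedim import AggShift
        y = {(i, u): 0.0 for i in Skill for u in AggShift}
        y[(Skill.TECHNICIAN, AggShift.MORNING)] = 2.0
        bad = StaffingSolution(x=x, y=y)
        assert any(v.family == "tsi" for v in check_feasibility(bad, inst))


class TestVariants:
    def test_single_cohort_counts_half_the_night_hours(self):
        night_only = solution((0, 0, 2, 2), (0, 0, 0, 0))
        params = ModelParameters.with_uniform_min_staff(0, prop=0.0)
        both = build_instance(10.0, params)
        single = build_instance(
            10.0, params, variant=ModelVariant(
                night_demand_hours="single_cohort"))
        assert max_delivered_hours(night_only.x, single) == pytest.approx(
            max_delivered_hours(night_only.x, both) / 2)

    def test_integer_aux_never_delivers_more_than_continuous(self):
        params = ModelParameters.with_uniform_min_staff(0, prop=0.0)
        cont = build_instance(50.0, params)
        integ = build_instance(50.0, params,
                               variant=ModelVariant(
                                   aux_integrality="integer"))
        for staffing in [solution((1, 2, 1, 1), (3, 2, 1, 1)),
                         solution((0, 1, 0, 0), (2, 2, 2, 2))]:
            assert (max_delivered_hours(staffing.x, integ)
                    <= max_delivered_hours(staffing.x, cont) + 1e-9)

    def test_pooled_tsi_scopes_relax_the_per_cell_link(self):
        params = ModelParameters.with_uniform_min_staff(0, prop=0.0)
        staffing = solution((2, 0, 0, 0), (0, 3, 1, 1))
        per_cell = build_instance(50.0, params)
        per_skill = build_instance(
            50.0, params, variant=ModelVariant(tsi_scope="per_skill"))
        pooled_global = build_instance(
            50.0, params, variant=ModelVariant(tsi_scope="global"))
        d_cell = max_delivered_hours(staffing.x, per_cell)
        d_skill = max_delivered_hours(staffing.x, per_skill)
        d_global = max_delivered_hours(staffing.x, pooled_global)
        assert d_cell <= d_skill + 1e-9 <= d_global + 2e-9

    def test_invalid_variant_value_rejected(self):
        with pytest.raises(ValueError, match="tsi_scope"):
            ModelVariant(tsi_scope="per_unit")


class TestShiftStructure:
    def test_night_cohort_lengths_must_match(self):
        lengths = {(i, s): 6.0 for i in Skill for s in Shift}
        lengths[(Skill.NURSE, Shift.NIGHT2)] = 12.0
        with pytest.raises(ValueError, match="night"):
            ShiftStructure(lengths)

    def test_from_hours_defaults(self):
        shifts = ShiftStructure.from_hours()
        assert shifts.length(Skill.NURSE, Shift.MORNING) == 6.0
        assert shifts.length(Skill.TECHNICIAN, Shift.NIGHT2) == 12.0
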
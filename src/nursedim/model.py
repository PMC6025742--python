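"""Phase II: the integer staffing model — instance construction, salary-cost
evaluation and feasibility checking.

The decision is how many nurses and nursing technicians to assign to each of
four shifts: morning, afternoon, and two night cohorts ("night 1" on odd
nights, "night 2" on even nights — night staff cannot work consecutive
nights, so the two cohorts alternate and must be equal in size).  A feasible
staffing must

1. deliver at least the required daily care hours (the pre-buffer staff
   levels, carried by auxiliary variables, do the delivering);
2. exceed those pre-buffer levels by the Technical Safety Index (TSI),
   the absence buffer;
3. contain at least a given fraction of nurses among all workers;
4. keep morning and afternoon head counts within a balance parameter per
   skill;
5. staff both night cohorts equally; and
6. respect a minimum head count per skill and shift.

The salary objective prices every assigned worker at shift length x hourly
rate, with a premium for night work; both night cohorts are paid.

The exact algebra linking staff to delivered hours admits several readings
(where the TSI buffer applies, whether auxiliary levels are integer, whether
one or both night cohorts' hours count toward a single day's demand, and who
is counted in the skill-mix ratio).  :class:`ModelVariant` makes the reading
explicit; the default is the combination under which the published reference
staffings of the case-study unit are all feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

from .demand import DemandProfile

__all__ = [
    "Skill",
    "Shift",
    "AggShift",
    "ShiftStructure",
    "CostSchedule",
    "ModelParameters",
    "ModelVariant",
    "StaffingInstance",
    "StaffingSolution",
    "Violation",
    "build_instance",
    "evaluate_cost",
    "check_feasibility",
    "max_delivered_hours",
    "best_aux_levels",
    "required_nurse_count",
]

_EPS = 1e-6


class Skill(Enum):
    NURSE = "nurse"
    TECHNICIAN = "technician"


class Shift(Enum):
    MORNING = "morning"
    AFTERNOON = "afternoon"
    NIGHT1 = "night1"
    NIGHT2 = "night2"

    @property
    def is_night(self) -> bool:
        return self in (Shift.NIGHT1, Shift.NIGHT2)

    @property
    def agg(self) -> "AggShift":
        if self is Shift.MORNING:
            return AggShift.MORNING
        if self is Shift.AFTERNOON:
            return AggShift.AFTERNOON
        return AggShift.NIGHT


class AggShift(Enum):
    """Shift index for the auxiliary (pre-TSI) staff levels.

    The two night cohorts share one auxiliary level because they back the
    same nightly service.
    """

    MORNING = "morning"
    AFTERNOON = "afternoon"
    NIGHT = "night"


CELLS: tuple[tuple[Skill, Shift], ...] = tuple(
    (i, s) for i in Skill for s in Shift)


@dataclass(frozen=True)
class ShiftStructure:
    """Shift lengths in hours per skill and shift.

    Defaults: 6 h morning, 6 h afternoon and 12 h night shifts for both
    skills — the pattern of the case-study hospital.
    """

    lengths: Mapping[tuple[Skill, Shift], float] = field(
        default_factory=lambda: {
            (i, s): 12.0 if s.is_night else 6.0 for i, s in CELLS})

    def __post_init__(self) -> None:
        for cell in CELLS:
            if cell not in self.lengths:
                raise ValueError(f"missing shift length for {cell}")
            if float(self.lengths[cell]) <= 0:
                raise ValueError(f"shift length for {cell} must be positive")
        for i in Skill:
            if not math.isclose(float(self.lengths[(i, Shift.NIGHT1)]),
                                float(self.lengths[(i, Shift.NIGHT2)])):
                raise ValueError(
                    f"night cohorts must have equal length for {i.value}")

    @classmethod
    def from_hours(cls, morning: float = 6.0, afternoon: float = 6.0,
                   night: float = 12.0, *,
                   per_skill: Mapping[Skill, tuple[float, float, float]]
                   | None = None) -> "ShiftStructure":
        """Build a structure from (morning, afternoon, night) hours.

        ``per_skill`` overrides the common hours for individual skills.
        """
        lengths: dict[tuple[Skill, Shift], float] = {}
        for i in Skill:
            m, a, n = (per_skill[i] if per_skill and i in per_skill
                       else (morning, afternoon, night))
            lengths[(i, Shift.MORNING)] = float(m)
            lengths[(i, Shift.AFTERNOON)] = float(a)
            lengths[(i, Shift.NIGHT1)] = float(n)
            lengths[(i, Shift.NIGHT2)] = float(n)
        return cls(lengths)

    def length(self, skill: Skill, shift: Shift) -> float:
        return float(self.lengths[(skill, shift)])

    @property
    def min_length(self) -> float:
        return min(float(v) for v in self.lengths.values())


@dataclass(frozen=True)
class CostSchedule:
    """Hourly salary rates in abstract monetary units (m.u.).

    Defaults: nurses earn 1 m.u. per hour, technicians 60% of that, and
    night work carries a 37.5% premium.  Both night cohorts are paid, so a
    unit night headcount (one worker in each cohort) costs twice the
    night-shift wage.
    """

    base_hourly_rate: Mapping[Skill, float] = field(
        default_factory=lambda: {Skill.NURSE: 1.0, Skill.TECHNICIAN: 0.6})
    night_premium: float = 0.375

    def __post_init__(self) -> None:
        for i in Skill:
            if i not in self.base_hourly_rate:
                raise ValueError(f"missing base rate for {i.value}")
            if float(self.base_hourly_rate[i]) <= 0:
                raise ValueError(f"base rate for {i.value} must be positive")
        if self.night_premium < 0:
            raise ValueError("night_premium must be non-negative")

    def hourly_rate(self, skill: Skill, shift: Shift) -> float:
        rate = float(self.base_hourly_rate[skill])
        if shift.is_night:
            rate *= 1.0 + self.night_premium
        return rate

    def worker_cost(self, skill: Skill, shift: Shift,
                    shifts: ShiftStructure) -> float:
        """Salary of one worker in one (skill, shift) cell."""
        return shifts.length(skill, shift) * self.hourly_rate(skill, shift)


def _uniform_staff(value: int) -> dict[tuple[Skill, Shift], int]:
    return {cell: int(value) for cell in CELLS}


@dataclass(frozen=True)
class ModelParameters:
    """Tunable Phase-II parameters.

    tsi
        Absence buffer fraction p; staffed levels must be at least (1+p)
        times the pre-buffer levels.  COFEN default 0.15.
    prop
        Minimum nurse fraction of the workforce.  ``None`` means "take it
        from the Phase-I demand profile".
    alpha
        Morning/afternoon balance bound per skill (max allowed head-count
        difference).
    min_staff
        Minimum head count per (skill, shift); default one worker in every
        cell.
    """

    tsi: float = 0.15
    prop: float | None = None
    alpha: Mapping[Skill, int] = field(
        default_factory=lambda: {Skill.NURSE: 1, Skill.TECHNICIAN: 1})
    min_staff: Mapping[tuple[Skill, Shift], int] = field(
        default_factory=lambda: _uniform_staff(1))

    def __post_init__(self) -> None:
        if self.tsi < 0:
            raise ValueError(f"tsi must be non-negative, got {self.tsi}")
        if self.prop is not None and not 0.0 <= self.prop < 1.0:
            raise ValueError(f"prop must lie in [0, 1), got {self.prop}")
        for i in Skill:
            a = self.alpha.get(i)
            if a is None or int(a) < 0 or int(a) != a:
                raise ValueError(
                    f"alpha[{i.value}] must be a non-negative integer")
        for cell in CELLS:
            m = self.min_staff.get(cell)
            if m is None or int(m) < 0 or int(m) != m:
                raise ValueError(
                    f"min_staff[{cell}] must be a non-negative integer")

    @classmethod
    def with_uniform_min_staff(cls, value: int, **kwargs) -> "ModelParameters":
        return cls(min_staff=_uniform_staff(value), **kwargs)


TsiScope = Literal["per_cell", "per_skill", "global"]
AuxIntegrality = Literal["continuous", "integer"]
NightDemandHours = Literal["both_cohorts", "single_cohort"]
PropCounting = Literal["all_employees", "per_day_staff"]


@dataclass(frozen=True)
class ModelVariant:
    """Selects one reading of the demand/TSI/skill-mix algebra.

    tsi_scope
        Where the (1+p) buffer links staff to auxiliary levels: per cell,
        pooled per skill, or pooled globally.
    aux_integrality
        Whether auxiliary pre-buffer levels are continuous or integer.
    night_demand_hours
        Whether both night cohorts' hours count toward one day's demand
        (each cohort serves every other night, but the guideline demand is
        stated per day and the model is solved for a single day) or only a
        single cohort's.
    prop_counting
        Whether the nurse fraction is taken over all employees of the pool
        or over the staff present on one day (one night cohort).
    """

    tsi_scope: TsiScope = "per_cell"
    aux_integrality: AuxIntegrality = "continuous"
    night_demand_hours: NightDemandHours = "both_cohorts"
    prop_counting: PropCounting = "all_employees"

    def __post_init__(self) -> None:
        checks = {
            "tsi_scope": ("per_cell", "per_skill", "global"),
            "aux_integrality": ("continuous", "integer"),
            "night_demand_hours": ("both_cohorts", "single_cohort"),
            "prop_counting": ("all_employees", "per_day_staff"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"{name} must be one of {allowed}, "
                    f"got {getattr(self, name)!r}")



@dataclass(frozen=True)
class StaffingInstance:
    """A fully numeric Phase-II problem."""

    demand_hours: float
    tsi: float
    prop: float
    alpha: Mapping[Skill, int]
    min_staff: Mapping[tuple[Skill, Shift], int]
    shifts: ShiftStructure
    costs: CostSchedule
    variant: ModelVariant
    upper_bounds: Mapping[tuple[Skill, Shift], int]

    def __post_init__(self) -> None:
        if self.demand_hours < 0:
            raise ValueError("demand_hours must be non-negative")
        if not 0.0 <= self.prop < 1.0:
            raise ValueError(f"prop must lie in [0, 1), got {self.prop}")
        if self.tsi < 0:
            raise ValueError("tsi must be non-negative")
        for cell in CELLS:
            if self.upper_bounds[cell] < self.min_staff[cell]:
                raise ValueError(
                    f"upper bound below minimum staff for {cell}")


class Violation(NamedTuple):
    """A violated constraint: identifier, family and violation magnitude."""

    name: str
    family: str
    slack: float


@dataclass(frozen=True)
class StaffingSolution:
    """Integer staff counts per (skill, shift), optional auxiliary levels
    and the salary objective."""

    x: Mapping[tuple[Skill, Shift], int]
    y: Mapping[tuple[Skill, AggShift], float] | None = None
    objective_cost: float | None = None

    def __post_init__(self) -> None:
        for cell in CELLS:
            if cell not in self.x:
                raise ValueError(f"missing staff count for {cell}")
            if int(self.x[cell]) < 0:
                raise ValueError(f"negative staff count for {cell}")

    @classmethod
    def from_vectors(cls, nurses: Sequence[int], technicians: Sequence[int],
                     y: Mapping[tuple[Skill, AggShift], float] | None = None,
                     objective_cost: float | None = None
                     ) -> "StaffingSolution":
        """Build from (morning, afternoon, night1, night2) count vectors."""
        if len(nurses) != 4 or len(technicians) != 4:
            raise ValueError("expected 4 counts per skill "
                             "(morning, afternoon, night1, night2)")
        x = {(Skill.NURSE, s): int(v) for s, v in zip(Shift, nurses)}
        x.update({(Skill.TECHNICIAN, s): int(v)
                  for s, v in zip(Shift, technicians)})
        return cls(x=x, y=y, objective_cost=objective_cost)

    def vector(self, skill: Skill) -> tuple[int, int, int, int]:
        return tuple(int(self.x[(skill, s)]) for s in Shift)  # type: ignore

    def skill_total(self, skill: Skill) -> int:
        return sum(self.vector(skill))

    @property
    def nurse_total(self) -> int:
        return self.skill_total(Skill.NURSE)

    @property
    def technician_total(self) -> int:
        return self.skill_total(Skill.TECHNICIAN)

    @property
    def total_staff(self) -> int:
        return self.nurse_total + self.technician_total


def required_nurse_count(total_staff: int, prop: float) -> int:
    """Smallest nurse head count n with n >= prop * total_staff."""
    if total_staff < 0:
        raise ValueError("total_staff must be non-negative")
    if not 0.0 <= prop < 1.0:
        raise ValueError(f"prop must lie in [0, 1), got {prop}")
    return max(0, math.ceil(prop * total_staff - _EPS))


def build_instance(demand: DemandProfile | float,
                   params: ModelParameters | None = None,
                   shifts: ShiftStructure | None = None,
                   costs: CostSchedule | None = None,
                   variant: ModelVariant | None = None,
                   upper_bound_cap: int | None = None) -> StaffingInstance:
    """Assemble a numeric staffing instance from Phase-I output.

    ``demand`` may be a :class:`~nursedim.demand.DemandProfile` (whose
    nurse ratio supplies ``prop`` unless ``params.prop`` overrides it) or a
    bare care-hours number (then ``params.prop`` must be set, or 0 is used).

    Variable upper bounds default to a provably safe envelope
    ``min_staff + ceil((1+p) * H / shortest shift length)``: even covering
    the whole buffered demand from the least productive cell never needs
    more workers.  ``upper_bound_cap`` tightens the envelope (useful for
    enumeration-based verification).
    """
    params = params or ModelParameters()
    shifts = shifts or ShiftStructure()
    costs = costs or CostSchedule()
    variant = variant or ModelVariant()
    if isinstance(demand, DemandProfile):
        hours = float(demand.care_hours)
        prop = params.prop if params.prop is not None else demand.prop
    else:
        hours = float(demand)
        prop = params.prop if params.prop is not None else 0.0
    if hours < 0:
        raise ValueError("care hours must be non-negative")
    envelope = math.ceil((1.0 + params.tsi) * hours / shifts.min_length
                         - _EPS) if hours > 0 else 0
    ub = {}
    for cell in CELLS:
        b = int(params.min_staff[cell]) + envelope
        if upper_bound_cap is not None:
            b = min(b, max(upper_bound_cap, int(params.min_staff[cell])))
        ub[cell] = b
    return StaffingInstance(
        demand_hours=hours, tsi=float(params.tsi), prop=float(prop),
        alpha=dict(params.alpha), min_staff=dict(params.min_staff),
        shifts=shifts, costs=costs, variant=variant, upper_bounds=ub)


def evaluate_cost(solution: StaffingSolution,
                  shifts: ShiftStructure | None = None,
                  costs: CostSchedule | None = None) -> float:
    """Total salary of a staffing in monetary units.

    Every worker in every cell is paid shift length x hourly rate (night
    premium applied); both night cohorts contribute.
    """
    shifts = shifts or ShiftStructure()
    costs = costs or CostSchedule()
    return float(sum(int(solution.x[cell]) * costs.worker_cost(*cell, shifts)
                     for cell in CELLS))


# ---------------------------------------------------------------------------
# Delivered care hours for a given staffing
# ---------------------------------------------------------------------------

def _demand_coeff(instance: StaffingInstance, skill: Skill,
                  agg: AggShift) -> float:
    """Care hours one unit of auxiliary level delivers toward the demand."""
    shifts = instance.shifts
    if agg is AggShift.MORNING:
        return shifts.length(skill, Shift.MORNING)
    if agg is AggShift.AFTERNOON:
        return shifts.length(skill, Shift.AFTERNOON)
    night = shifts.length(skill, Shift.NIGHT1)
    if instance.variant.night_demand_hours == "both_cohorts":
        return 2.0 * night
    return night


def _tsi_weight(agg: AggShift) -> float:
    # One auxiliary night unit is backed by a worker in each cohort.
    return 2.0 if agg is AggShift.NIGHT else 1.0


def _cell_aux_cap(instance: StaffingInstance,
                  x: Mapping[tuple[Skill, Shift], int],
                  skill: Skill, agg: AggShift) -> float:
    """Largest auxiliary level the per-cell TSI link allows for given x."""
    buffer = 1.0 + instance.tsi
    if agg is AggShift.MORNING:
        return x[(skill, Shift.MORNING)] / buffer
    if agg is AggShift.AFTERNOON:
        return x[(skill, Shift.AFTERNOON)] / buffer
    n1 = x[(skill, Shift.NIGHT1)]
    n2 = x[(skill, Shift.NIGHT2)]
    if instance.variant.night_demand_hours == "both_cohorts":
        return (n1 + n2) / (2.0 * buffer)
    return min(n1, n2) / buffer


def _best_budget_value(budget: float, options: Iterable[tuple[float, float]],
                       integer: bool) -> float:
    """Maximize delivered hours from a single TSI budget.

    ``options`` are (demand coefficient, budget weight) pairs.  Continuous:
    pour the whole budget into the best coefficient/weight ratio.  Integer:
    night units weigh 2, day units 1, so scan the night allocation.
    """
    options = list(options)
    if budget <= 0 or not options:
        return 0.0
    if not integer:
        return budget * max(c / w for c, w in options)
    day = [c for c, w in options if w == 1.0]
    night = [c for c, w in options if w == 2.0]
    best_day = max(day) if day else 0.0
    best_night = max(night) if night else 0.0
    best = 0.0
    for b in range(int(budget // 2) + 1):
        value = b * best_night + math.floor(budget - 2 * b + _EPS) * best_day
        best = max(best, value)
    if not night:
        best = math.floor(budget + _EPS) * best_day
    return best


def best_aux_levels(x: Mapping[tuple[Skill, Shift], int],
                    instance: StaffingInstance
                    ) -> dict[tuple[Skill, AggShift], float]:
    """Auxiliary levels maximizing delivered hours for a given staffing.

    Only defined cell-wise for the per-cell TSI scope; pooled scopes admit
    many optimal splits, so use :func:`max_delivered_hours` there.
    """
    if instance.variant.tsi_scope != "per_cell":
        raise ValueError("cell-wise auxiliary levels are only defined for "
                         "the per_cell TSI scope")
    integer = instance.variant.aux_integrality == "integer"
    levels = {}
    for i in Skill:
        for u in AggShift:
            cap = _cell_aux_cap(instance, x, i, u)
            levels[(i, u)] = float(math.floor(cap + _EPS)) if integer else cap
    return levels


def max_delivered_hours(x: Mapping[tuple[Skill, Shift], int],
                        instance: StaffingInstance) -> float:
    """Most care hours a staffing can deliver within its TSI links."""
    variant = instance.variant
    integer = variant.aux_integrality == "integer"
    buffer = 1.0 + instance.tsi
    if variant.tsi_scope == "per_cell":
        levels = best_aux_levels(x, instance)
        return sum(_demand_coeff(instance, i, u) * levels[(i, u)]
                   for i in Skill for u in AggShift)
    if variant.tsi_scope == "per_skill":
        total = 0.0
        for i in Skill:
            budget = sum(x[(i, s)] for s in Shift) / buffer
            options = [(_demand_coeff(instance, i, u), _tsi_weight(u))
                       for u in AggShift]
            total += _best_budget_value(budget, options, integer)
        return total
    budget = sum(x[cell] for cell in CELLS) / buffer
    options = [(_demand_coeff(instance, i, u), _tsi_weight(u))
               for i in Skill for u in AggShift]
    return _best_budget_value(budget, options, integer)


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------

def _prop_counts(instance: StaffingInstance,
                 x: Mapping[tuple[Skill, Shift], int]) -> tuple[int, int]:
    if instance.variant.prop_counting == "all_employees":
        shifts: tuple[Shift, ...] = tuple(Shift)
    else:  # staff present on one day: one night cohort on duty
        shifts = (Shift.MORNING, Shift.AFTERNOON, Shift.NIGHT1)
    nurses = sum(int(x[(Skill.NURSE, s)]) for s in shifts)
    total = nurses + sum(int(x[(Skill.TECHNICIAN, s)]) for s in shifts)
    return nurses, total


def check_feasibility(solution: StaffingSolution,
                      instance: StaffingInstance,
                      tol: float = _EPS) -> list[Violation]:
    """All constraint violations of a candidate staffing (empty = feasible).

    When the solution carries no auxiliary levels, the checker grants it the
    best attainable levels for its head counts before judging the demand
    and TSI constraints.
    """
    x = {cell: int(solution.x[cell]) for cell in CELLS}
    out: list[Violation] = []

    if solution.y is not None:
        y = {key: float(v) for key, v in solution.y.items()}
        for key, v in y.items():
            if v < -tol:
                out.append(Violation(f"aux_nonneg[{key[0].value},"
                                     f"{key[1].value}]", "aux_nonneg", -v))
        if instance.variant.aux_integrality == "integer":
            for key, v in y.items():
                frac = abs(v - round(v))
                if frac > tol:
                    out.append(Violation(
                        f"aux_integrality[{key[0].value},{key[1].value}]",
                        "aux_integrality", frac))
        delivered = sum(_demand_coeff(instance, i, u) * y[(i, u)]
                        for i in Skill for u in AggShift)
        out.extend(_tsi_violations(instance, x, y, tol))
    else:
        delivered = max_delivered_hours(x, instance)

    short = instance.demand_hours - delivered
    if short > tol:
        out.append(Violation("demand", "demand", short))

    nurses, total = _prop_counts(instance, x)
    short = instance.prop * total - nurses
    if short > tol:
        out.append(Violation("skill_mix", "skill_mix", short))

    for i in Skill:
        gap = abs(x[(i, Shift.MORNING)] - x[(i, Shift.AFTERNOON)])
        if gap > int(instance.alpha[i]):
            out.append(Violation(f"balance[{i.value}]", "balance",
                                 gap - int(instance.alpha[i])))
        diff = abs(x[(i, Shift.NIGHT1)] - x[(i, Shift.NIGHT2)])
        if diff != 0:
            out.append(Violation(f"night_parity[{i.value}]", "night_parity",
                                 float(diff)))

    for cell in CELLS:
        short_cover = int(instance.min_staff[cell]) - x[cell]
        if short_cover > 0:
            out.append(Violation(
                f"min_cover[{cell[0].value},{cell[1].value}]", "min_cover",
                float(short_cover)))
    return out


def _tsi_violations(instance: StaffingInstance,
                    x: Mapping[tuple[Skill, Shift], int],
                    y: Mapping[tuple[Skill, AggShift], float],
                    tol: float) -> list[Violation]:
    buffer = 1.0 + instance.tsi
    out: list[Violation] = []
    scope = instance.variant.tsi_scope
    if scope == "per_cell":
        for i in Skill:
            for u in AggShift:
                cap = _cell_aux_cap(instance, x, i, u)
                if y[(i, u)] > cap + tol:
                    out.append(Violation(f"tsi[{i.value},{u.value}]", "tsi",
                                         y[(i, u)] - cap))
    elif scope == "per_skill":
        for i in Skill:
            used = sum(_tsi_weight(u) * y[(i, u)] for u in AggShift)
            budget = sum(x[(i, s)] for s in Shift) / buffer
            if used > budget + tol:
                out.append(Violation(f"tsi[{i.value}]", "tsi", used - budget))
    else:
        used = sum(_tsi_weight(u) * y[(i, u)]
                   for i in Skill for u in AggShift)
        budget = sum(x[cell] for cell in CELLS) / buffer
        if used > budget + tol:
            out.append(Violation("tsi", "tsi", used - budget))
    return out
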
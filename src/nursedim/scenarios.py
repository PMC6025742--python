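"""What-if analyses on top of the two-phase method.

``sweep`` re-solves one day's staffing over a grid of minimum-cover and
balance parameters (the sensitivity analysis a planner runs before fixing
unit rules); ``multiday`` runs Phase I + Phase II for a run of consecutive
censuses; ``compare_actual`` sets a multi-day report against a constant
actual roster to expose per-skill surpluses and shortfalls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .demand import CareStandard, DemandProfile, PatientCensus, phase1
from .model import (
    CELLS,
    CostSchedule,
    ModelParameters,
    ModelVariant,
    Shift,
    ShiftStructure,
    Skill,
    StaffingSolution,
    build_instance,
)
from .solver import InfeasibleInstanceError, solve

__all__ = [
    "SweepResult",
    "MultiDayReport",
    "sweep",
    "multiday",
    "compare_actual",
]

_SHIFT_COLS = {
    Shift.MORNING: "morning",
    Shift.AFTERNOON: "afternoon",
    Shift.NIGHT1: "night1",
    Shift.NIGHT2: "night2",
}


def _staffing_columns(solution: StaffingSolution | None) -> dict:
    cols: dict = {}
    for skill, prefix in ((Skill.NURSE, "nurse"), (Skill.TECHNICIAN, "tech")):
        for shift, name in _SHIFT_COLS.items():
            cols[f"{prefix}_{name}"] = (
                None if solution is None else int(solution.x[(skill, shift)]))
        cols[f"{prefix}_total"] = (
            None if solution is None else solution.skill_total(skill))
    cols["total_staff"] = None if solution is None else solution.total_staff
    cols["total_cost"] = (
        None if solution is None or solution.objective_cost is None
        else float(solution.objective_cost))
    return cols


@dataclass(frozen=True)
class SweepResult:
    """Grid of solved instances over (min_staff, alpha) parameter values."""

    table: pd.DataFrame
    solutions: dict[tuple[int, int], StaffingSolution | None]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep(demand: DemandProfile,
          base_params: ModelParameters | None = None,
          min_staff_values: Sequence[int] = (1, 2, 3),
          alpha_values: Sequence[int] = (1, 2, 3),
          shifts: ShiftStructure | None = None,
          costs: CostSchedule | None = None,
          variant: ModelVariant | None = None) -> SweepResult:
    """Solve one instance per (min_staff, alpha) grid point.

    ``min_staff`` is applied uniformly to every (skill, shift) cell and
    ``alpha`` to both skills, matching how the sensitivity of the model is
    usually explored.  Infeasible grid points are flagged in their row
    rather than aborting the sweep.
    """
    if not min_staff_values or not alpha_values:
        raise ValueError("parameter grids must be non-empty")
    base_params = base_params or ModelParameters()
    rows = []
    solutions: dict[tuple[int, int], StaffingSolution | None] = {}
    for m in min_staff_values:
        for a in alpha_values:
            params = replace(
                base_params,
                alpha={Skill.NURSE: int(a), Skill.TECHNICIAN: int(a)},
                min_staff={cell: int(m) for cell in CELLS})
            instance = build_instance(demand, params, shifts=shifts,
                                      costs=costs, variant=variant)
            row = {"min_staff": int(m), "alpha": int(a)}
            try:
                solution = solve(instance)
                row["status"] = "optimal"
            except InfeasibleInstanceError as err:
                solution = None
                row["status"] = "infeasible: " + ", ".join(err.families)
            solutions[(int(m), int(a))] = solution
            row.update(_staffing_columns(solution))
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), solutions=solutions)


@dataclass(frozen=True)
class MultiDayReport:
    """Per-day demand and optimal staffing for consecutive censuses."""

    table: pd.DataFrame
    solutions: dict[object, StaffingSolution | None]

    @classmethod
    def from_solutions(cls, dates: Sequence[object],
                       solutions: Sequence[StaffingSolution],
                       status: str = "reference") -> "MultiDayReport":
        """Tabulate externally given per-day staffings (e.g. a published
        reference roster) in the multi-day report layout."""
        rows = [{"date": d, "status": status, **_staffing_columns(s)}
                for d, s in zip(dates, solutions)]
        return cls(table=pd.DataFrame(rows),
                   solutions=dict(zip(dates, solutions)))

    @property
    def min_total_staff(self) -> int:
        return int(self.table["total_staff"].dropna().min())

    @property
    def max_total_staff(self) -> int:
        return int(self.table["total_staff"].dropna().max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def multiday(censuses: Iterable[PatientCensus],
             standard: CareStandard | None = None,
             params: ModelParameters | None = None,
             shifts: ShiftStructure | None = None,
             costs: CostSchedule | None = None,
             variant: ModelVariant | None = None,
             ratio_rule: str = "weighted") -> MultiDayReport:
    """Phase I followed by Phase II for each census in turn.

    The per-day nurse fraction comes from Phase I unless ``params.prop``
    pins it; the TSI follows the care standard unless ``params`` overrides
    it.  A day whose instance is infeasible is flagged in its row and the
    report still covers the remaining days.
    """
    standard = standard or CareStandard()
    params = params or ModelParameters(tsi=standard.tsi)
    censuses = list(censuses)
    if not censuses:
        raise ValueError("multiday needs at least one census")
    rows = []
    solutions: dict[object, StaffingSolution | None] = {}
    for census in censuses:
        profile = phase1(census, standard, ratio_rule=ratio_rule)
        row = {
            "unit": census.unit,
            "date": census.date,
            "total_patients": profile.census.total_patients,
            "minimal": profile.census.minimal,
            "intermediary": profile.census.intermediary,
            "semi_intensive": profile.census.semi_intensive,
            "intensive": profile.census.intensive,
            "care_hours": profile.care_hours,
            "nurse_ratio_pct": profile.nurse_ratio_pct,
        }
        instance = build_instance(profile, params, shifts=shifts,
                                  costs=costs, variant=variant)
        try:
            solution = solve(instance)
            row["status"] = "optimal"
        except InfeasibleInstanceError as err:
            solution = None
            row["status"] = "infeasible: " + ", ".join(err.families)
        solutions[census.date] = solution
        row.update(_staffing_columns(solution))
        rows.append(row)
    return MultiDayReport(table=pd.DataFrame(rows), solutions=solutions)


def compare_actual(report: MultiDayReport, actual_nurses: int,
                   actual_technicians: int) -> pd.DataFrame:
    """Per-day difference between model staffing and a constant roster.

    Positive differences mean the model asks for more workers than the
    roster holds (a shortfall of the actual staffing); negative means the
    roster exceeds the modelled need.
    """
    if actual_nurses < 0 or actual_technicians < 0:
        raise ValueError("actual staff counts must be non-negative")
    t = report.table
    out = pd.DataFrame({
        "date": t["date"],
        "model_nurses": t["nurse_total"],
        "model_technicians": t["tech_total"],
        "model_total": t["total_staff"],
        "actual_nurses": actual_nurses,
        "actual_technicians": actual_technicians,
        "actual_total": actual_nurses + actual_technicians,
    })
    out["nurse_diff"] = out["model_nurses"] - out["actual_nurses"]
    out["technician_diff"] = (out["model_technicians"]
                              - out["actual_technicians"])
    out["total_diff"] = out["model_total"] - out["actual_total"]
    return out
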
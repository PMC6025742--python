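"""File interfaces: census CSV ingestion and the YAML configuration tree.

A census file is a UTF-8 comma-separated table with the exact header

    unit,date,minimal,intermediary,semi_intensive,intensive,unclassified

one row per unit-day, ISO-8601 dates and non-negative integer counts.

The configuration file is a flat YAML key tree; every key is optional and
omitted keys take the packaged defaults (COFEN care standard, 6/6/12-hour
shifts, 1.0/0.6 m.u. hourly rates with a 37.5% night premium, one worker
minimum per cell, balance bound 1, default model variant).  See
``DEFAULT_CONFIG_YAML`` for the full schema with defaults spelled out.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .demand import CareStandard, PatientCensus, SeverityCategory
from .model import (
    CELLS,
    CostSchedule,
    ModelParameters,
    ModelVariant,
    Shift,
    ShiftStructure,
    Skill,
)

__all__ = [
    "CENSUS_COLUMNS",
    "ConfigError",
    "CensusParseError",
    "Config",
    "read_census_csv",
    "write_census_csv",
    "load_config",
    "DEFAULT_CONFIG_YAML",
]

CENSUS_COLUMNS = ("unit", "date", "minimal", "intermediary",
                  "semi_intensive", "intensive", "unclassified")


class CensusParseError(ValueError):
    """A census file failed validation; the message names row and column."""


class ConfigError(ValueError):
    """A configuration file failed validation."""


def read_census_csv(path) -> list[PatientCensus]:
    """Read and validate a census CSV into :class:`PatientCensus` rows."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CensusParseError(f"{path}: file is empty (expected header "
                               f"{','.join(CENSUS_COLUMNS)})") from None
    got = tuple(df.columns)
    if got != CENSUS_COLUMNS:
        unknown = [c for c in got if c not in CENSUS_COLUMNS]
        missing = [c for c in CENSUS_COLUMNS if c not in got]
        parts = []
        if missing:
            parts.append(f"missing columns: {', '.join(missing)}")
        if unknown:
            parts.append(f"unknown columns: {', '.join(unknown)}")
        if not parts:
            parts.append(f"columns out of order: got {', '.join(got)}")
        raise CensusParseError(f"{path}: invalid header — {'; '.join(parts)}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        counts = {}
        for col in CENSUS_COLUMNS[2:]:
            raw = getattr(row, col).strip()
            try:
                value = int(raw)
            except ValueError:
                raise CensusParseError(
                    f"{path}: row {idx}, column {col!r}: "
                    f"expected an integer, got {raw!r}") from None
            if value < 0:
                raise CensusParseError(
                    f"{path}: row {idx}, column {col!r}: "
                    f"count must be non-negative, got {value}")
            counts[col] = value
        try:
            date = _dt.date.fromisoformat(row.date.strip())
        except ValueError:
            raise CensusParseError(
                f"{path}: row {idx}, column 'date': expected ISO-8601 "
                f"date, got {row.date!r}") from None
        out.append(PatientCensus(unit=row.unit, date=date, **counts))
    return out


def write_census_csv(censuses: Sequence[PatientCensus], path) -> None:
    """Write censuses in the documented CSV layout (round-trips with
    :func:`read_census_csv`)."""
    rows = [{
        "unit": c.unit,
        "date": c.date.isoformat() if c.date else "",
        "minimal": c.minimal,
        "intermediary": c.intermediary,
        "semi_intensive": c.semi_intensive,
        "intensive": c.intensive,
        "unclassified": c.unclassified,
    } for c in censuses]
    pd.DataFrame(rows, columns=list(CENSUS_COLUMNS)).to_csv(path, index=False)


@dataclass(frozen=True)
class Config:
    """Validated parameter bundle for the whole pipeline."""

    care_standard: CareStandard = field(default_factory=CareStandard)
    shift_structure: ShiftStructure = field(default_factory=ShiftStructure)
    cost_schedule: CostSchedule = field(default_factory=CostSchedule)
    model_parameters: ModelParameters = field(
        default_factory=lambda: ModelParameters())
    variant: ModelVariant = field(default_factory=ModelVariant)
    oracle_cap: int = 8


DEFAULT_CONFIG_YAML = """\
# nursedim configuration — every key optional; values below are defaults.
care_standard:
  hours_per_patient:         # care hours per patient per day
    minimal: 3.8
    intermediary: 5.6
    semi_intensive: 9.4
    intensive: 17.9
  nurse_pct:                 # minimum nurse percentage per category
    minimal: 33
    intermediary: 33
    semi_intensive: 42
    intensive: 52
  tsi: 0.15                  # absence buffer fraction
shift_structure:             # shift lengths in hours, per skill
  nurse:      {morning: 6, afternoon: 6, night: 12}
  technician: {morning: 6, afternoon: 6, night: 12}
cost_schedule:
  base_hourly_rate: {nurse: 1.0, technician: 0.6}   # m.u. per hour
  night_premium: 0.375
model_parameters:
  tsi: 0.15
  prop: null                 # null = take the nurse fraction from Phase I
  alpha: {nurse: 1, technician: 1}
  min_staff:                 # per skill and shift
    nurse:      {morning: 1, afternoon: 1, night1: 1, night2: 1}
    technician: {morning: 1, afternoon: 1, night1: 1, night2: 1}
variant:
  tsi_scope: per_cell        # per_cell | per_skill | global
  aux_integrality: continuous  # continuous | integer
  night_demand_hours: both_cohorts  # both_cohorts | single_cohort
  prop_counting: all_employees      # all_employees | per_day_staff
solver:
  oracle_cap: 8
"""


def _reject_unknown(mapping: Mapping[str, Any], allowed: Sequence[str],
                    where: str) -> None:
    unknown = [k for k in mapping if k not in allowed]
    if unknown:
        raise ConfigError(
            f"unknown key(s) under {where}: {', '.join(map(str, unknown))}; "
            f"allowed: {', '.join(allowed)}")


def _category_map(raw: Mapping[str, Any], where: str,
                  defaults: Mapping[SeverityCategory, float]
                  ) -> dict[SeverityCategory, float]:
    _reject_unknown(raw, [c.value for c in SeverityCategory], where)
    out = dict(defaults)
    for key, value in raw.items():
        out[SeverityCategory(key)] = float(value)
    return out


def _parse_care_standard(raw: Mapping[str, Any]) -> CareStandard:
    _reject_unknown(raw, ["hours_per_patient", "nurse_pct", "tsi"],
                    "care_standard")
    default = CareStandard()
    kwargs: dict[str, Any] = {}
    if "hours_per_patient" in raw:
        kwargs["hours_per_patient"] = _category_map(
            raw["hours_per_patient"], "care_standard.hours_per_patient",
            default.hours_per_patient)
    if "nurse_pct" in raw:
        kwargs["nurse_pct"] = _category_map(
            raw["nurse_pct"], "care_standard.nurse_pct", default.nurse_pct)
    if "tsi" in raw:
        kwargs["tsi"] = float(raw["tsi"])
    return CareStandard(**kwargs)


def _parse_shift_structure(raw: Mapping[str, Any]) -> ShiftStructure:
    _reject_unknown(raw, [i.value for i in Skill], "shift_structure")
    per_skill = {}
    for skill in Skill:
        if skill.value not in raw:
            continue
        hours = raw[skill.value]
        _reject_unknown(hours, ["morning", "afternoon", "night"],
                        f"shift_structure.{skill.value}")
        per_skill[skill] = (float(hours.get("morning", 6.0)),
                            float(hours.get("afternoon", 6.0)),
                            float(hours.get("night", 12.0)))
    return ShiftStructure.from_hours(per_skill=per_skill)


def _parse_cost_schedule(raw: Mapping[str, Any]) -> CostSchedule:
    _reject_unknown(raw, ["base_hourly_rate", "night_premium"],
                    "cost_schedule")
    kwargs: dict[str, Any] = {}
    if "base_hourly_rate" in raw:
        rates = raw["base_hourly_rate"]
        _reject_unknown(rates, [i.value for i in Skill],
                        "cost_schedule.base_hourly_rate")
        default = CostSchedule()
        merged = dict(default.base_hourly_rate)
        for key, value in rates.items():
            merged[Skill(key)] = float(value)
        kwargs["base_hourly_rate"] = merged
    if "night_premium" in raw:
        kwargs["night_premium"] = float(raw["night_premium"])
    return CostSchedule(**kwargs)


def _parse_min_staff(raw: Mapping[str, Any]
                     ) -> dict[tuple[Skill, Shift], int]:
    _reject_unknown(raw, [i.value for i in Skill],
                    "model_parameters.min_staff")
    out = {cell: 1 for cell in CELLS}
    for skill_key, per_shift in raw.items():
        skill = Skill(skill_key)
        _reject_unknown(per_shift, [s.value for s in Shift],
                        f"model_parameters.min_staff.{skill_key}")
        for shift_key, value in per_shift.items():
            out[(skill, Shift(shift_key))] = int(value)
    return out


def _parse_model_parameters(raw: Mapping[str, Any],
                            tsi_default: float) -> ModelParameters:
    _reject_unknown(raw, ["tsi", "prop", "alpha", "min_staff"],
                    "model_parameters")
    kwargs: dict[str, Any] = {"tsi": float(raw.get("tsi", tsi_default))}
    if raw.get("prop") is not None:
        kwargs["prop"] = float(raw["prop"])
    if "alpha" in raw:
        _reject_unknown(raw["alpha"], [i.value for i in Skill],
                        "model_parameters.alpha")
        alpha = {Skill.NURSE: 1, Skill.TECHNICIAN: 1}
        for key, value in raw["alpha"].items():
            alpha[Skill(key)] = int(value)
        kwargs["alpha"] = alpha
    if "min_staff" in raw:
        kwargs["min_staff"] = _parse_min_staff(raw["min_staff"])
    return ModelParameters(**kwargs)


def _parse_variant(raw: Mapping[str, Any]) -> ModelVariant:
    allowed = ["tsi_scope", "aux_integrality", "night_demand_hours",
               "prop_counting"]
    _reject_unknown(raw, allowed, "variant")
    return ModelVariant(**{k: str(v) for k, v in raw.items()})


def load_config(path=None) -> Config:
    """Load and validate a YAML configuration; ``None`` gives defaults.

    Schema violations raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return Config()
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if raw is None:
        return Config()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, ["care_standard", "shift_structure",
                          "cost_schedule", "model_parameters", "variant",
                          "solver"], "the top level")
    try:
        care = _parse_care_standard(raw.get("care_standard", {}) or {})
        shifts = _parse_shift_structure(raw.get("shift_structure", {}) or {})
        costs = _parse_cost_schedule(raw.get("cost_schedule", {}) or {})
        params = _parse_model_parameters(raw.get("model_parameters", {})
                                         or {}, tsi_default=care.tsi)
        variant = _parse_variant(raw.get("variant", {}) or {})
        solver_raw = raw.get("solver", {}) or {}
        _reject_unknown(solver_raw, ["oracle_cap"], "solver")
        cap = int(solver_raw.get("oracle_cap", 8))
    except ConfigError:
        raise
    except (TypeError, ValueError, KeyError) as err:
        raise ConfigError(f"{path}: {err}") from err
    return Config(care_standard=care, shift_structure=shifts,
                  cost_schedule=costs, model_parameters=params,
                  variant=variant, oracle_cap=cap)
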
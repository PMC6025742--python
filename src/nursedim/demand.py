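"""Phase I: convert a severity-stratified patient census into daily care-hour
demand and a minimum nurse-to-staff percentage.

Brazilian COFEN guidelines (Resolution 293/2004) prescribe, per inpatient and
per day, a minimum number of nursing care hours that depends on the patient's
illness-severity category, and a minimum percentage of nurses (as opposed to
nursing technicians) in the workforce that depends on the unit's patient mix.
This module implements both computations.  Two rules for the nurse percentage
are provided:

``dominant``
    The percentage of the severity category with the largest head count —
    the rule as stated in the guideline text.
``weighted``
    The care-hour-weighted average of the category percentages, rounded to
    the nearest integer percent.  This is the package default: it agrees
    with published per-day values for a real unit where the dominant rule
    does not (a minimal-care-dominated census would always yield 33%).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Literal, Mapping

__all__ = [
    "SeverityCategory",
    "PatientCensus",
    "CareStandard",
    "DemandProfile",
    "normalize_census",
    "care_hours",
    "nurse_ratio_dominant",
    "nurse_ratio_weighted",
    "phase1",
]


class SeverityCategory(Enum):
    """Illness-severity categories, ordered by increasing acuity."""

    MINIMAL = "minimal"
    INTERMEDIARY = "intermediary"
    SEMI_INTENSIVE = "semi_intensive"
    INTENSIVE = "intensive"

    @property
    def acuity(self) -> int:
        """Position in the acuity ordering (0 = minimal care)."""
        return list(SeverityCategory).index(self)


def _check_count(name: str, value: int) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class PatientCensus:
    """Head count of inpatients per severity category for one unit-day.

    ``unclassified`` patients have not (yet) been assigned a severity
    category; by convention they are counted as needing intermediary care
    (see :func:`normalize_census`).
    """

    minimal: int = 0
    intermediary: int = 0
    semi_intensive: int = 0
    intensive: int = 0
    unclassified: int = 0
    unit: str = ""
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        for cat in ("minimal", "intermediary", "semi_intensive",
                    "intensive", "unclassified"):
            _check_count(cat, getattr(self, cat))

    def count(self, category: SeverityCategory) -> int:
        return int(getattr(self, category.value))

    @property
    def total_patients(self) -> int:
        return (self.minimal + self.intermediary + self.semi_intensive
                + self.intensive + self.unclassified)

    @property
    def is_normalized(self) -> bool:
        return self.unclassified == 0


_DEFAULT_HOURS = {
    SeverityCategory.MINIMAL: 3.8,
    SeverityCategory.INTERMEDIARY: 5.6,
    SeverityCategory.SEMI_INTENSIVE: 9.4,
    SeverityCategory.INTENSIVE: 17.9,
}
_DEFAULT_NURSE_PCT = {
    SeverityCategory.MINIMAL: 33.0,
    SeverityCategory.INTERMEDIARY: 33.0,
    SeverityCategory.SEMI_INTENSIVE: 42.0,
    SeverityCategory.INTENSIVE: 52.0,
}


@dataclass(frozen=True)
class CareStandard:
    """Care-hour coefficients and nurse percentages per severity category.

    Defaults are the COFEN 293/2004 values: 3.8 / 5.6 / 9.4 / 17.9 hours of
    nursing care per patient per day and nurse percentages 33 / 33 / 42 / 52,
    plus a 15% Technical Safety Index (TSI) absence buffer.
    """

    hours_per_patient: Mapping[SeverityCategory, float] = field(
        default_factory=lambda: dict(_DEFAULT_HOURS))
    nurse_pct: Mapping[SeverityCategory, float] = field(
        default_factory=lambda: dict(_DEFAULT_NURSE_PCT))
    tsi: float = 0.15

    def __post_init__(self) -> None:
        cats = list(SeverityCategory)
        for mapping, label in ((self.hours_per_patient, "hours_per_patient"),
                               (self.nurse_pct, "nurse_pct")):
            missing = [c for c in cats if c not in mapping]
            if missing:
                raise ValueError(f"{label} missing categories: {missing}")
        hours = [float(self.hours_per_patient[c]) for c in cats]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError(
                "hours_per_patient must strictly increase with acuity, "
                f"got {hours}")
        for c in cats:
            pct = float(self.nurse_pct[c])
            if not 0.0 < pct <= 100.0:
                raise ValueError(f"nurse_pct[{c.value}] must be in (0, 100], "
                                 f"got {pct}")
        if self.tsi < 0:
            raise ValueError(f"tsi must be non-negative, got {self.tsi}")


@dataclass(frozen=True)
class DemandProfile:
    """Phase-I output: daily care hours and the minimum nurse percentage."""

    care_hours: float
    nurse_ratio_pct: int
    census: PatientCensus | None = None

    @property
    def prop(self) -> float:
        """Nurse ratio as the fraction used by the staffing model."""
        return self.nurse_ratio_pct / 100.0


def normalize_census(census: PatientCensus) -> PatientCensus:
    """Fold unclassified patients into the intermediary-care count.

    Unclassified inpatients are treated as needing intermediary care; the
    total patient count is conserved.
    """
    if census.unclassified == 0:
        return census
    return replace(
        census,
        intermediary=census.intermediary + census.unclassified,
        unclassified=0,
    )


def _require_normalized(census: PatientCensus) -> None:
    if not census.is_normalized:
        raise ValueError(
            "census has unclassified patients; apply normalize_census first")


def care_hours(census: PatientCensus, standard: CareStandard) -> float:
    """Required nursing care hours per day for a normalized census.

    Returns sum over categories of (patient count x hours per patient).
    """
    _require_normalized(census)
    return float(sum(census.count(c) * float(standard.hours_per_patient[c])
                     for c in SeverityCategory))


def nurse_ratio_dominant(census: PatientCensus,
                         standard: CareStandard) -> int:
    """Nurse percentage of the severity category with the most patients.

    Ties are broken toward the higher-acuity category (the safer, i.e.
    higher-percentage, reading).
    """
    _require_normalized(census)
    if census.total_patients == 0:
        raise ValueError("no patients: nurse ratio is undefined")
    # max() keeps the last maximum when keys tie and categories are scanned
    # in increasing acuity, which is exactly the documented tie-break.
    best = max(SeverityCategory, key=lambda c: (census.count(c), c.acuity))
    return int(round(float(standard.nurse_pct[best])))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def nurse_ratio_weighted(census: PatientCensus,
                         standard: CareStandard) -> int:
    """Care-hour-weighted nurse percentage, rounded half away from zero.

    Each category contributes its percentage weighted by the care hours its
    patients generate, so a few high-acuity patients raise the ratio above
    the dominant category's value.
    """
    _require_normalized(census)
    total = care_hours(census, standard)
    if total <= 0:
        raise ValueError("zero care hours: weighted nurse ratio is undefined")
    weighted = sum(
        census.count(c) * float(standard.hours_per_patient[c])
        * float(standard.nurse_pct[c])
        for c in SeverityCategory)
    return _round_half_away(weighted / total)


RatioRule = Literal["dominant", "weighted"]


def phase1(census: PatientCensus, standard: CareStandard | None = None,
           ratio_rule: RatioRule = "weighted") -> DemandProfile:
    """Run Phase I: care hours plus the selected nurse-ratio rule.

    ``standard`` defaults to the COFEN values.
    """
    standard = standard or CareStandard()
    norm = normalize_census(census)
    hours = care_hours(norm, standard)
    if ratio_rule == "dominant":
        ratio = nurse_ratio_dominant(norm, standard)
    elif ratio_rule == "weighted":
        ratio = nurse_ratio_weighted(norm, standard)
    else:
        raise ValueError(f"unknown ratio_rule {ratio_rule!r}; "
                         "expected 'dominant' or 'weighted'")
    return DemandProfile(care_hours=hours, nurse_ratio_pct=ratio, census=norm)
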
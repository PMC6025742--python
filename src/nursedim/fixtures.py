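"""Packaged case-study data and a seeded synthetic census generator.

The eight-day census of the "In. U 4th floor PRT/CNV" inpatient unit of
Hospital São José (Porto Alegre, September 2016) ships with the package,
together with the published per-day reference staffings and the unit's
actual roster, so every analysis is runnable without downloads.  The data
are stored as CSV inside the package so the CLI can consume them exactly
like user-supplied files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .demand import PatientCensus
from .model import StaffingSolution

__all__ = [
    "HSJCase",
    "hsj_eight_days",
    "hsj_census_path",
    "random_census",
    "DEFAULT_COUNT_RANGES",
]

# Unit roster actually employed during the study period (constant).
HSJ_ACTUAL_NURSES = 4
HSJ_ACTUAL_TECHNICIANS = 22


@dataclass(frozen=True)
class HSJCase:
    """The packaged eight-day case: censuses, published per-day demand
    figures, published reference staffings and the actual roster."""

    censuses: tuple[PatientCensus, ...]
    care_hours: tuple[float, ...]
    nurse_ratio_pct: tuple[int, ...]
    reference_solutions: Mapping[_dt.date, StaffingSolution]
    actual_nurses: int
    actual_technicians: int

    @property
    def dates(self) -> tuple[_dt.date, ...]:
        return tuple(c.date for c in self.censuses)


def _data_file(name: str):
    return resources.files("nursedim.data").joinpath(name)


def hsj_census_path() -> str:
    """Filesystem path of the packaged eight-day census CSV."""
    return str(_data_file("hsj_table2.csv"))


def hsj_eight_days() -> HSJCase:
    """Load the packaged eight-day case study."""
    census_df = pd.read_csv(_data_file("hsj_table2.csv"))
    refs_df = pd.read_csv(_data_file("hsj_reference_solutions.csv"))
    censuses = tuple(
        PatientCensus(
            minimal=int(r.minimal), intermediary=int(r.intermediary),
            semi_intensive=int(r.semi_intensive), intensive=int(r.intensive),
            unclassified=int(r.unclassified), unit=str(r.unit),
            date=_dt.date.fromisoformat(str(r.date)))
        for r in census_df.itertuples())
    refs = {}
    for r in refs_df.itertuples():
        refs[_dt.date.fromisoformat(str(r.date))] = (
            StaffingSolution.from_vectors(
                nurses=(r.nurse_morning, r.nurse_afternoon,
                        r.nurse_night1, r.nurse_night2),
                technicians=(r.tech_morning, r.tech_afternoon,
                             r.tech_night1, r.tech_night2)))
    return HSJCase(
        censuses=censuses,
        care_hours=tuple(float(v) for v in refs_df["care_hours"]),
        nurse_ratio_pct=tuple(int(v) for v in refs_df["nurse_ratio_pct"]),
        reference_solutions=refs,
        actual_nurses=HSJ_ACTUAL_NURSES,
        actual_technicians=HSJ_ACTUAL_TECHNICIANS,
    )


# Per-category draw ranges (inclusive) shaped like the case-study unit: a
# general inpatient ward dominated by minimal care, occasional unclassified
# admissions, intensive care essentially absent.
DEFAULT_COUNT_RANGES: dict[str, tuple[int, int]] = {
    "minimal": (10, 25),
    "intermediary": (5, 12),
    "semi_intensive": (0, 4),
    "intensive": (0, 1),
    "unclassified": (0, 3),
}


def random_census(seed: int, n_days: int,
                  count_ranges: Mapping[str, tuple[int, int]] | None = None,
                  unit: str = "synthetic unit",
                  start_date: _dt.date = _dt.date(2016, 9, 7)
                  ) -> list[PatientCensus]:
    """Reproducible synthetic censuses for consecutive days.

    Per-category counts are drawn uniformly (inclusive) from
    ``count_ranges``; the same seed always yields the same table.
    """
    ranges = dict(DEFAULT_COUNT_RANGES)
    if count_ranges:
        ranges.update(count_ranges)
    for cat, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid count range for {cat}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for d in range(int(n_days)):
        counts = {cat: int(rng.integers(lo, hi + 1))
                  for cat, (lo, hi) in ranges.items()}
        out.append(PatientCensus(unit=unit,
                                 date=start_date + _dt.timedelta(days=d),
                                 **counts))
    return out
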
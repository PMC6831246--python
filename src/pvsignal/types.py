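"""Domain types for individual case safety reports (ICSRs).

An ICSR is one spontaneous adverse-event report: patient covariates (sex,
age), one or more drugs with a suspected/concomitant role, one or more
adverse-event preferred terms (PT), a WHO-UMC causality category, and
seriousness information. Reports are held in a :class:`ReportSet`, the
in-memory container every pipeline stage consumes and produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Iterator


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    MISSING = "missing"


class Causality(str, Enum):
    """WHO-UMC causality assessment categories (consumed, never computed)."""

    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    UNASSESSABLE = "unassessable"
    UNCLASSIFIED = "unclassified"
    MISSING = "missing"


class ReportType(str, Enum):
    SPONTANEOUS = "spontaneous"
    POST_MARKETING_SURVEILLANCE = "post_marketing_surveillance"
    LITERATURE = "literature"
    OTHER = "other"


class Reporter(str, Enum):
    DOCTOR = "doctor"
    PHARMACIST = "pharmacist"
    NURSE = "nurse"
    CONSUMER = "consumer"
    OTHER = "other"
    UNKNOWN = "unknown"


class SeriousnessType(str, Enum):
    HOSPITALIZATION = "hospitalization"
    OTHER_INCLUDING_DEATH = "other_including_death"
    NONE = "none"


class AgeGroup(str, Enum):
    """Age strata: [0, 20), [20, 40), [40, 60), [60, inf)."""

    LT20 = "lt20"
    A20_39 = "20_39"
    A40_59 = "40_59"
    GE60 = "ge60"


def age_group_of(age_years: float | None) -> AgeGroup | None:
    """Map an age in years onto the four analysis strata; ``None`` if missing."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return None
    if age_years < 0:
        raise ValueError(f"age_years must be non-negative, got {age_years}")
    if age_years < 20:
        return AgeGroup.LT20
    if age_years < 40:
        return AgeGroup.A20_39
    if age_years < 60:
        return AgeGroup.A40_59
    return AgeGroup.GE60


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DrugEntry:
    """One drug on a report: ATC code (may be missing) and suspected role."""

    atc_code: str | None
    suspected: bool = True


@dataclass
class IcsrReport:
    """One spontaneous adverse-event report."""

    report_id: str
    is_initial: bool
    report_year: int
    report_type: ReportType
    reporter: Reporter
    sex: Sex
    age_years: float | None
    causality: Causality
    serious: bool
    seriousness_type: SeriousnessType
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not self.serious and self.seriousness_type != SeriousnessType.NONE:
            raise ValueError(
                f"report {self.report_id}: serious=False requires seriousness_type=none"
            )
        if self.serious and self.seriousness_type == SeriousnessType.NONE:
            raise ValueError(
                f"report {self.report_id}: serious=True requires a seriousness type"
            )
        if self.age_years is not None and not math.isnan(self.age_years) and self.age_years < 0:
            raise ValueError(f"report {self.report_id}: negative age {self.age_years}")

    @property
    def age_group(self) -> AgeGroup | None:
        return age_group_of(self.age_years)

    def suspected_drugs(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.suspected]

    def has_drug(self, atc_code: str, suspected_only: bool = True) -> bool:
        return any(
            d.atc_code == atc_code and (d.suspected or not suspected_only)
            for d in self.drugs
        )

    def copy(self, **changes) -> "IcsrReport":
        out = replace(self, **changes)
        if "drugs" not in changes:
            out.drugs = list(self.drugs)
        if "events" not in changes:
            out.events = list(self.events)
        return out


class ReportSet:
    """An ordered collection of reports with unique report ids.

    Supports iteration, ``len``, and indexing; rows rejected at parse time
    travel alongside in :attr:`rejects` so nothing is silently dropped.
    """

    def __init__(self, reports: Iterable[IcsrReport] = (), rejects: list[dict] | None = None):
        self._reports: list[IcsrReport] = list(reports)
        seen: set[str] = set()
        for r in self._reports:
            if r.report_id in seen:
                raise ValueError(f"duplicate report_id {r.report_id!r} in ReportSet")
            seen.add(r.report_id)
        self.rejects: list[dict] = rejects or []

    def __iter__(self) -> Iterator[IcsrReport]:
        return iter(self._reports)

    def __len__(self) -> int:
        return len(self._reports)

    def __getitem__(self, idx):
        return self._reports[idx]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self._reports == other._reports

    def count_with_drug(self, atc_code: str, suspected_only: bool = True) -> int:
        return sum(1 for r in self if r.has_drug(atc_code, suspected_only))

    def subset_with_drug(self, atc_code: str, suspected_only: bool = True) -> "ReportSet":
        return ReportSet(r for r in self if r.has_drug(atc_code, suspected_only))
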
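"""Domain records for longitudinal claims data.

The raw inputs are the four per-patient event streams found in any
administrative claims extract — diagnoses, drug claims, procedures and
coverage (eligibility) intervals — plus a demographics row.  Everything
downstream (cohort selection, line-of-therapy construction, comorbidity
scoring, attrition tables) consumes these records.

Dates are ``datetime.date`` throughout; durations in months use the
365.25/12 = 30.4375 days-per-month convention so that month arithmetic is
deterministic and calendar-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Optional

DAYS_PER_MONTH = 30.4375

SEX_VALUES = ("male", "female")
ROUTE_VALUES = ("oral", "parenteral")
SOURCE_KINDS = ("claims", "emr")
COVERAGE_KINDS = ("medical", "pharmacy")


def months_between(start: date, end: date) -> float:
    """Day span from *start* to *end* expressed in 30.4375-day months."""
    return (end - start).days / DAYS_PER_MONTH


@dataclass(frozen=True, order=True)
class DrugClaim:
    """One dispensing or administration of an anti-myeloma agent.

    ``days_supply`` is the number of days the claim covers; parenteral
    administrations, which carry no supply in real claims, are assigned a
    default cadence upstream (see :class:`lotline.config.LotRules`).
    """

    date: date
    agent: str
    days_supply: Optional[int] = None  # None = administration without supply
    route: str = "oral"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.days_supply is not None and self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.route not in ROUTE_VALUES:
            raise ValueError(f"route must be one of {ROUTE_VALUES}, got {self.route!r}")


@dataclass(frozen=True, order=True)
class DiagnosisEvent:
    """A dated diagnosis code (condition resolution happens via a code map)."""

    date: date
    code: str
    patient_id: str = ""


@dataclass(frozen=True, order=True)
class ProcedureEvent:
    """A dated procedure; ``kind`` is ``"ASCT"`` for stem-cell transplant."""

    date: date
    kind: str = "other"
    patient_id: str = ""


@dataclass(frozen=True, order=True)
class CoverageInterval:
    """A continuous span of medical or pharmacy insurance eligibility."""

    start: date
    end: date
    kind: str = "medical"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"coverage start {self.start} after end {self.end}")
        if self.kind not in COVERAGE_KINDS:
            raise ValueError(f"coverage kind must be one of {COVERAGE_KINDS}")


@dataclass
class PatientRecord:
    """All longitudinal data for one patient.

    ``source_kind`` controls the follow-up-end rule: ``"claims"`` sources end
    follow-up when continuous eligibility ends, ``"emr"`` sources on the last
    date of observed activity.  ``truth`` carries generator-side ground truth
    (planned journey, outcomes) for simulated patients; it is never
    serialized and is absent for patients read from disk.
    """

    patient_id: str
    birth_year: int
    sex: Optional[str] = None
    race: str = "unknown"
    death_date: Optional[date] = None
    source_kind: str = "claims"
    diagnosis_events: list[DiagnosisEvent] = field(default_factory=list)
    drug_claims: list[DrugClaim] = field(default_factory=list)
    procedure_events: list[ProcedureEvent] = field(default_factory=list)
    coverage: list[CoverageInterval] = field(default_factory=list)
    truth: Optional[dict] = None

    def sort_events(self) -> None:
        self.diagnosis_events.sort(key=lambda e: (e.date, e.code))
        self.drug_claims.sort(key=lambda c: (c.date, c.agent))
        self.procedure_events.sort(key=lambda p: (p.date, p.kind))
        self.coverage.sort(key=lambda c: (c.kind, c.start, c.end))


@dataclass(frozen=True)
class ExposureInterval:
    """Continuous exposure span for one agent (end = last covered day)."""

    agent: str
    start: date
    end: date
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exposure start {self.start} after end {self.end}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class LineOfTherapy:
    """A numbered treatment line.

    ``end_reason`` is one of ``gap`` (a regimen agent lapsed for the
    discontinuation gap), ``new_agent`` (a non-regimen agent started),
    ``followup_end`` or ``death``.  ``induction`` / ``consolidation_present``
    are transplant-phase annotations attached after segmentation.
    """

    patient_id: str
    lot_number: int
    start: date
    end: date
    regimen_agents: frozenset[str]
    end_reason: str
    regimen_category: Optional[str] = None
    induction: bool = False
    consolidation_present: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"line start {self.start} after end {self.end}")
        if not self.regimen_agents:
            raise ValueError("regimen_agents must be nonempty")

    @property
    def duration_months(self) -> float:
        # inclusive day count: a line starting and ending the same day is
        # one treated day (~0.03 months), not zero
        return ((self.end - self.start).days + 1) / DAYS_PER_MONTH

    def agents_label(self) -> str:
        return ";".join(sorted(self.regimen_agents))


@dataclass
class CohortMember:
    """An included study patient with derived eligibility attributes."""

    patient_id: str
    index_diagnosis_date: date
    age_at_diagnosis: int
    age_category: str
    sex: str
    race: str
    transplant_status: str  # "transplant" | "non_transplant"
    followup_end: date
    followup_months_from_first_lot: Optional[float] = None
    death_date: Optional[date] = None
    source_kind: str = "claims"


@dataclass(frozen=True)
class FilterStep:
    criterion: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class FilterLog:
    """Ordered attrition-of-the-cohort bookkeeping, one row per criterion."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, criterion: str, n_before: int, n_after: int) -> None:
        if self.steps and self.steps[-1].n_after != n_before:
            raise ValueError("filter log steps must chain: n_after != next n_before")
        self.steps.append(FilterStep(criterion, n_before, n_before - n_after, n_after))

    @property
    def final_n(self) -> int:
        return self.steps[-1].n_after if self.steps else 0

    def to_rows(self) -> list[dict]:
        return [dataclasses.asdict(s) for s in self.steps]


def age_category(age: int) -> str:
    """Study age bands: <65, 65-74, 75-84, >=85."""
    if age < 65:
        return "<65"
    if age < 75:
        return "65-74"
    if age < 85:
        return "75-84"
    return ">=85"


AGE_CATEGORIES = ("<65", "65-74", "75-84", ">=85")
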
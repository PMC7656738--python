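"""Cohort selection: study inclusion rules, follow-up windows, strata.

Criteria are applied in a fixed order, each emitting a row of the
:class:`~lotline.records.FilterLog`:

1. index MM diagnosis on/after the floor date (2007-01-01),
2. known sex,
3. medical AND pharmacy coverage active on the index date,
4. >=365 days of continuous coverage before index (look-back),
5. no prior-malignancy diagnosis in the 365 days before index,
6. >=1 line of therapy constructed by the LOT engine within follow-up.

Follow-up ends, for claims-type sources, with the continuous coverage
interval containing the index date (a configurable gap between intervals
may be bridged); for EMR-type sources, on the last date of observed
activity.  Death truncates follow-up when earlier.  A patient received
ASCT iff an ASCT procedure falls inside [index, follow-up end]; this
defines the transplant stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

from .comorbidity import CodeMap, default_code_map
from .config import CohortCriteria, LotRules
from .lot import build_patient_lines
from .records import (
    CohortMember,
    CoverageInterval,
    FilterLog,
    LineOfTherapy,
    PatientRecord,
    age_category,
    months_between,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortResult",
    "build_cohort",
    "determine_followup_end",
    "followup_months",
    "index_diagnosis_date",
]


def index_diagnosis_date(patient: PatientRecord, code_map: CodeMap) -> Optional[date]:
    """First recorded MM diagnosis (the index diagnosis), if any."""
    mm_codes = code_map.codes_for("multiple_myeloma")
    dates = [e.date for e in patient.diagnosis_events if e.code in mm_codes]
    return min(dates) if dates else None


def _merged_coverage(
    intervals: Sequence[CoverageInterval], kind: str, bridge_days: int
) -> list[tuple[date, date]]:
    spans = sorted((c.start, c.end) for c in intervals if c.kind == kind)
    merged: list[tuple[date, date]] = []
    for s, e in spans:
        if merged and (s - merged[-1][1]).days - 1 <= bridge_days:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _containing(spans: list[tuple[date, date]], day: date) -> Optional[tuple[date, date]]:
    for s, e in spans:
        if s <= day <= e:
            return (s, e)
    return None


def determine_followup_end(
    patient: PatientRecord,
    index_date: Optional[date] = None,
    coverage_gap_days: int = 0,
    code_map: Optional[CodeMap] = None,
) -> Optional[date]:
    """Follow-up end under the source's rule, truncated at death.

    Claims sources: the earlier end of the merged medical and pharmacy
    coverage intervals containing the index date; returns ``None`` (signals
    criterion-3 ineligibility) if either kind is inactive at index.
    EMR sources: the maximum date over all observed events.
    """
    if index_date is None:
        index_date = index_diagnosis_date(patient, code_map or default_code_map())
        if index_date is None:
            return None
    if patient.source_kind == "emr":
        dates = [e.date for e in patient.diagnosis_events]
        dates += [c.date for c in patient.drug_claims]
        dates += [p.date for p in patient.procedure_events]
        if not dates:
            return None
        end = max(dates)
    else:
        med = _containing(_merged_coverage(patient.coverage, "medical", coverage_gap_days), index_date)
        pha = _containing(_merged_coverage(patient.coverage, "pharmacy", coverage_gap_days), index_date)
        if med is None or pha is None:
            return None
        end = min(med[1], pha[1])
    if patient.death_date is not None and patient.death_date < end:
        end = patient.death_date
    return end


def followup_months(member: CohortMember, first_lot_start: date) -> float:
    """Months of follow-up from the start of the first line of therapy."""
    return months_between(first_lot_start, member.followup_end)


@dataclass
class CohortResult:
    members: list[CohortMember]
    filter_log: FilterLog
    lines: dict[str, list[LineOfTherapy]] = field(default_factory=dict)

    def lines_of(self, patient_id: str) -> list[LineOfTherapy]:
        return self.lines.get(patient_id, [])


def build_cohort(
    population: Sequence[PatientRecord],
    criteria: Optional[CohortCriteria] = None,
    lot_rules: Optional[LotRules] = None,
    code_map: Optional[CodeMap] = None,
) -> CohortResult:
    """Apply the inclusion criteria in order and derive member attributes.

    Patients with an MM claim but no demographics row cannot occur here
    (records are demographics-anchored); a patient with no MM diagnosis at
    all is dropped before criterion 1 with a log notice.
    """
    criteria = criteria or CohortCriteria()
    lot_rules = lot_rules or LotRules()
    code_map = code_map or default_code_map()
    log = FilterLog()

    current: list[tuple[PatientRecord, date]] = []
    for p in population:
        idx = index_diagnosis_date(p, code_map)
        if idx is None:
            logger.info("patient %s has no MM diagnosis; excluded pre-criteria", p.patient_id)
            continue
        current.append((p, idx))

    # 1. index diagnosis on/after the floor date
    n0 = len(current)
    current = [(p, idx) for p, idx in current if idx >= criteria.index_floor_date]
    log.add("index_on_or_after_floor", n0, len(current))

    # 2. known sex
    n0 = len(current)
    current = [(p, idx) for p, idx in current if p.sex in ("male", "female")]
    log.add("known_sex", n0, len(current))

    # 3. medical and pharmacy coverage active on index date
    n0 = len(current)
    kept = []
    followups: dict[str, date] = {}
    for p, idx in current:
        end = determine_followup_end(p, idx, criteria.coverage_gap_days, code_map)
        if end is None or end < idx:
            continue
        followups[p.patient_id] = end
        kept.append((p, idx))
    current = kept
    log.add("coverage_active_at_index", n0, len(current))

    # 4. continuous look-back coverage before index
    n0 = len(current)
    kept = []
    for p, idx in current:
        need = idx - timedelta(days=criteria.lookback_days)
        ok = True
        if p.source_kind == "claims":
            for kind in ("medical", "pharmacy"):
                span = _containing(
                    _merged_coverage(p.coverage, kind, criteria.coverage_gap_days), idx)
                if span is None or span[0] > need:
                    ok = False
        else:
            # EMR sources carry no eligibility table; the look-back is the
            # record history itself, so the criterion passes by construction
            ok = True
        if ok:
            kept.append((p, idx))
    current = kept
    log.add("lookback_coverage", n0, len(current))

    # 5. no prior malignancy within the look-back year
    n0 = len(current)
    prior_codes: set[str] = set()
    for cat in criteria.prior_malignancy_categories:
        prior_codes |= set(code_map.category_codes.get(cat, ()))
    kept = []
    for p, idx in current:
        lo = idx - timedelta(days=criteria.lookback_days)
        has_prior = any(
            e.code in prior_codes and lo <= e.date <= idx - timedelta(days=1)
            for e in p.diagnosis_events
        )
        if not has_prior:
            kept.append((p, idx))
    current = kept
    log.add("no_prior_malignancy", n0, len(current))

    # 6. at least one constructed line of therapy
    n0 = len(current)
    members: list[CohortMember] = []
    lines_by_patient: dict[str, list[LineOfTherapy]] = {}
    for p, idx in current:
        end = followups[p.patient_id]
        lines = build_patient_lines(
            p.drug_claims, p.procedure_events, end, lot_rules,
            death_date=p.death_date, patient_id=p.patient_id)
        if not lines:
            continue
        lines_by_patient[p.patient_id] = lines
        has_asct = any(
            pr.kind == "ASCT" and idx <= pr.date <= end for pr in p.procedure_events
        )
        age = idx.year - p.birth_year
        member = CohortMember(
            patient_id=p.patient_id,
            index_diagnosis_date=idx,
            age_at_diagnosis=age,
            age_category=age_category(age),
            sex=p.sex,  # type: ignore[arg-type]
            race=p.race,
            transplant_status="transplant" if has_asct else "non_transplant",
            followup_end=end,
            death_date=p.death_date,
            source_kind=p.source_kind,
        )
        member.followup_months_from_first_lot = followup_months(member, lines[0].start)
        members.append(member)
    log.add("received_at_least_one_lot", n0, len(members))

    return CohortResult(members=members, filter_log=log, lines=lines_by_patient)
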
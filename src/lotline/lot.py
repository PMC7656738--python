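"""Line-of-therapy construction from drug claims.

The algorithm implements the standard claims-based LOT rule set for
multiple myeloma: a line starts at the first administration of any
anti-myeloma agent; agents whose exposure begins within the
regimen-formation window join the line's regimen; the line continues until
either (a) an agent outside the regimen is administered (``new_agent``),
(b) a regimen agent's exposure lapses for at least the discontinuation gap
— 60 days by default — while follow-up continues (``gap``), or (c)
follow-up or death intervenes.  The next line starts at the next claim
after the line end.

Events are ordered by *when the rule fires*: a new agent fires on its first
administration day, a discontinuation fires on the day the gap requirement
completes (last covered day + gap).  This matches a literal day-by-day scan
of the rule text; when both fire simultaneously, ``new_agent`` wins because
the new agent's start defines the next line unambiguously.

Transplant phases: the line active at (or most recently before) ASCT is the
induction line.  Post-ASCT treatment that starts within ~4 months of ASCT,
persists at least ~1 month beyond it, and uses the induction regimen or a
superset of it, is consolidation — folded into the induction line rather
than opening a new one.
"""

from __future__ import annotations

import logging
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .config import LotRules
from .records import (
    DrugClaim,
    ExposureInterval,
    LineOfTherapy,
    ProcedureEvent,
)
from .regimen import classify_regimen

logger = logging.getLogger(__name__)

__all__ = [
    "build_exposure_intervals",
    "segment_lines",
    "attach_transplant_phases",
    "build_patient_lines",
    "lot_duration_months",
]


def _claim_cover(claim: DrugClaim, rules: LotRules) -> tuple[date, date]:
    """Covered span of one claim; administrations recorded without a days
    supply use the configured administration cadence."""
    supply = claim.days_supply
    if supply is None:
        supply = rules.administration_default_supply_days
    return claim.date, claim.date + timedelta(days=supply - 1)


def build_exposure_intervals(
    claims: Iterable[DrugClaim],
    rules: Optional[LotRules] = None,
    followup_end: Optional[date] = None,
) -> list[ExposureInterval]:
    """Merge per-agent claim coverage into continuous exposure intervals.

    Each claim covers ``[date, date + days_supply - 1]``; spans of the same
    agent separated by at most ``merge_gap_days`` uncovered days merge into
    one interval.  Claims for agents outside the dictionary are skipped with
    a warning by the caller that owns the agent dictionary; here every agent
    string is taken at face value.  Coverage is clipped to ``followup_end``
    when given.
    """
    rules = rules or LotRules()
    by_agent: dict[str, list[tuple[date, date]]] = {}
    for c in claims:
        start, end = _claim_cover(c, rules)
        if followup_end is not None:
            if start > followup_end:
                continue
            end = min(end, followup_end)
        by_agent.setdefault(c.agent, []).append((start, end))

    out: list[ExposureInterval] = []
    for agent in sorted(by_agent):
        spans = sorted(by_agent[agent])
        cur_s, cur_e = spans[0]
        pid = ""
        for s, e in spans[1:]:
            gap = (s - cur_e).days - 1
            if gap <= rules.merge_gap_days:
                cur_e = max(cur_e, e)
            else:
                out.append(ExposureInterval(agent, cur_s, cur_e, pid))
                cur_s, cur_e = s, e
        out.append(ExposureInterval(agent, cur_s, cur_e, pid))
    out.sort(key=lambda iv: (iv.start, iv.agent))
    return out


def _first_gap_event(
    intervals: Sequence[ExposureInterval],
    followup_end: date,
    gap_days: int,
) -> Optional[tuple[date, date]]:
    """Earliest qualifying discontinuation for one agent.

    Returns (event_day, line_end_day) where event_day is the day the gap
    requirement completes.  A terminal lapse (no further exposure) qualifies
    only if follow-up extends through the full gap.
    """
    for prev, nxt in zip(intervals, intervals[1:]):
        gap = (nxt.start - prev.end).days - 1
        if gap >= gap_days:
            return prev.end + timedelta(days=gap_days), prev.end
    last_end = intervals[-1].end
    if (followup_end - last_end).days >= gap_days:
        return last_end + timedelta(days=gap_days), last_end
    return None


def _union_intervals(intervals: Sequence[ExposureInterval]) -> list[ExposureInterval]:
    """Merge intervals of possibly different agents into abutting-merged union spans."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[date, date]] = []
    for s, e in spans:
        if merged and (s - merged[-1][1]).days <= 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [ExposureInterval("*", s, e) for s, e in merged]


def segment_lines(
    claims: Sequence[DrugClaim],
    followup_end: date,
    rules: Optional[LotRules] = None,
    death_date: Optional[date] = None,
    patient_id: str = "",
) -> list[LineOfTherapy]:
    """Segment one patient's drug claims into ordered lines of therapy.

    Claims after ``followup_end`` are ignored and coverage is clipped to it.
    Exposure intervals are rebuilt from the claims remaining after each line
    break so a refill of a previously seen agent can anchor the next line.
    """
    rules = rules or LotRules()
    known = [c for c in sorted(claims, key=lambda c: (c.date, c.agent)) if c.date <= followup_end]
    lines: list[LineOfTherapy] = []
    remaining = known
    while remaining:
        line = _segment_one(remaining, followup_end, rules, death_date, patient_id)
        lines.append(line)
        remaining = [c for c in remaining if c.date > line.end]
    for k, line in enumerate(lines, start=1):
        line.lot_number = k
        line.regimen_category = classify_regimen(line.regimen_agents).label
    return lines


def _segment_one(
    remaining: Sequence[DrugClaim],
    followup_end: date,
    rules: LotRules,
    death_date: Optional[date],
    patient_id: str,
) -> LineOfTherapy:
    intervals = build_exposure_intervals(remaining, rules, followup_end)
    by_agent: dict[str, list[ExposureInterval]] = {}
    for iv in intervals:
        by_agent.setdefault(iv.agent, []).append(iv)
    first_start = {a: ivs[0].start for a, ivs in by_agent.items()}

    line_start = min(first_start.values())
    window_end = line_start + timedelta(days=rules.regimen_formation_window_days)
    regimen = {a for a, s in first_start.items() if s <= window_end}

    steroid_exempt = (not rules.steroids_trigger_new_line)
    exempt_agents = rules.steroid_agents if steroid_exempt else frozenset()
    # agents whose lapse can end the line / whose late start opens a new one
    trigger_regimen = {a for a in regimen if a not in exempt_agents} or set(regimen)

    # (event_day, priority, end_day, reason); lower priority wins ties
    candidates: list[tuple[date, int, date, str]] = []

    # (a) new agent administered after the formation window
    late = [
        s for a, s in first_start.items()
        if s > window_end and a not in exempt_agents
    ]
    if late:
        s = min(late)
        candidates.append((s, 0, s - timedelta(days=1), "new_agent"))

    # (b) discontinuation: in any_agent mode the first regimen agent whose
    # exposure lapses >= gap days ends the line; in all_agents mode the line
    # ends only when the union coverage of the regimen lapses that long
    if rules.line_end_mode == "any_agent_discontinued":
        gap_events = []
        for a in sorted(trigger_regimen):
            ev = _first_gap_event(by_agent[a], followup_end, rules.discontinuation_gap_days)
            if ev is not None:
                gap_events.append(ev)
        if gap_events:
            event_day, end_day = min(gap_events)
            candidates.append((event_day, 1, end_day, "gap"))
    else:
        union = _union_intervals(
            [iv for a in trigger_regimen for iv in by_agent[a]]
        )
        ev = _first_gap_event(union, followup_end, rules.discontinuation_gap_days)
        if ev is not None:
            candidates.append((ev[0], 1, ev[1], "gap"))

    # (c) follow-up end / death
    censor_reason = "death" if (death_date is not None and followup_end >= death_date) else "followup_end"
    candidates.append((followup_end, 2, followup_end, censor_reason))

    _, _, end_day, reason = min(candidates, key=lambda t: (t[0], t[1]))

    # late steroid add-ons join the regimen without opening a new line
    if steroid_exempt:
        for a in sorted(rules.steroid_agents & set(first_start)):
            if line_start <= first_start[a] <= end_day:
                regimen.add(a)

    return LineOfTherapy(
        patient_id=patient_id,
        lot_number=0,
        start=line_start,
        end=max(end_day, line_start),
        regimen_agents=frozenset(regimen),
        end_reason=reason,
    )


def attach_transplant_phases(
    lines: list[LineOfTherapy],
    procedures: Iterable[ProcedureEvent],
    rules: Optional[LotRules] = None,
    followup_end: Optional[date] = None,
) -> list[LineOfTherapy]:
    """Annotate induction/consolidation around the first ASCT and fold
    qualifying consolidation into the induction line.

    Mutates and returns ``lines``.  Patients whose last treatment-related
    event is the ASCT itself keep a single line.
    """
    rules = rules or LotRules()
    ascts = sorted(p.date for p in procedures if p.kind == "ASCT")
    if followup_end is not None:
        ascts = [d for d in ascts if d <= followup_end]
    if not ascts or not lines:
        return lines
    asct = ascts[0]

    ind = None
    for line in lines:
        if line.start <= asct:
            ind = line
    if ind is None:
        logger.warning("ASCT on %s precedes any exposure; ignored for phase labeling", asct)
        return lines
    ind.induction = True

    persist_until = asct + timedelta(days=rules.consolidation_min_duration_days)
    if ind.end >= persist_until:
        # treatment simply continued through transplant long enough
        ind.consolidation_present = True
        return lines

    idx = lines.index(ind)
    nxt = lines[idx + 1] if idx + 1 < len(lines) else None
    if (
        nxt is not None
        and nxt.start > asct
        and (nxt.start - asct).days <= rules.consolidation_window_days
        and nxt.end >= persist_until
        and nxt.regimen_agents >= ind.regimen_agents
    ):
        ind.end = nxt.end
        ind.end_reason = nxt.end_reason
        ind.consolidation_present = True
        lines.remove(nxt)
        for k, line in enumerate(lines, start=1):
            line.lot_number = k
    return lines


def build_patient_lines(
    claims: Sequence[DrugClaim],
    procedures: Iterable[ProcedureEvent],
    followup_end: date,
    rules: Optional[LotRules] = None,
    death_date: Optional[date] = None,
    patient_id: str = "",
) -> list[LineOfTherapy]:
    """Segment claims and attach transplant phases in one step."""
    rules = rules or LotRules()
    lines = segment_lines(claims, followup_end, rules, death_date, patient_id)
    return attach_transplant_phases(lines, procedures, rules, followup_end)


def lot_duration_months(line: LineOfTherapy) -> float:
    """Treatment duration in 30.4375-day months (rounded only at presentation).

    Counts inclusive covered days, so a single-day line is ~0.03 months and a
    line spanning 365 covered days is ~11.99 months.
    """
    return line.duration_months
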
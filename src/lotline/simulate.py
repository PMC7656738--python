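"""Synthetic claims-population generator.

Emulates a newly-diagnosed multiple-myeloma claims cohort: each patient
gets an index MM diagnosis, a 1-year-plus look-back of medical and pharmacy
coverage, 180-day pre-index comorbidity diagnoses, and a treatment journey
drawn line by line — at each line the patient continues to the next line
with the stratum's continuation probability, dies with its death
probability, or is censored treatment-free.  Claims are emitted to realize
each planned line exactly: every regimen agent is refilled at its cadence
so coverage spans the line with no internal gap, lines are separated by
treatment-free gaps longer than the discontinuation rule, and transplant
patients receive an ASCT (optionally followed by a consolidation segment
that the line-of-therapy engine folds back into line 1).

Each simulated :class:`~lotline.records.PatientRecord` carries a ``truth``
dict with the planned lines and outcomes, so downstream stages can be
tested against known ground truth.  A configurable fraction of patients
receives deliberate protocol violations (a mid-line >=60-day gap or a late
add-on agent) to exercise the engine; these patients' observed lines will
not match their planned ones, and ``truth["violation"]`` flags them.

Determinism: the same seed and config produce byte-identical tables;
different seeds produce distinct patient-id sequences (ids embed the seed).
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

import numpy as np

from .config import AGENT_ROUTES, SimulationConfig
from .records import (
    CoverageInterval,
    DiagnosisEvent,
    DrugClaim,
    PatientRecord,
    ProcedureEvent,
    DAYS_PER_MONTH,
)
from .regimen import CATEGORY_AGENT_SETS
from .comorbidity import default_code_map

__all__ = ["generate_population"]

_STUDY_COMORBIDITY_WINDOW = 180
_EPOCH = date(2000, 1, 1)


def _days(d: date) -> int:
    return (d - _EPOCH).days


def _date(days: int) -> date:
    return _EPOCH + timedelta(days=int(days))


def _choice(rng: np.random.Generator, weighted: dict[str, float]) -> str:
    keys = sorted(weighted)
    p = np.array([weighted[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _draw_agents(rng: np.random.Generator, category: str) -> tuple[str, ...]:
    options = CATEGORY_AGENT_SETS[category]
    w = np.array([wt for _, wt in options], dtype=float)
    idx = int(rng.choice(len(options), p=w / w.sum()))
    return options[idx][0]


def _duration_days(rng: np.random.Generator, mu: float, sigma: float) -> int:
    months = float(rng.lognormal(mean=mu, sigma=sigma))
    months = min(max(months, 0.25), 60.0)
    return max(1, int(round(months * DAYS_PER_MONTH)))


def _gap_days(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    g = cfg.gap_model
    return g.min_days + int(round(float(rng.lognormal(g.log_mu, g.log_sigma))))


def _emit_line_claims(
    pid: str, agents: tuple[str, ...], start: int, end: int, cfg: SimulationConfig
) -> list[DrugClaim]:
    """Refill claims so each agent covers [start, end] with no internal gap."""
    claims: list[DrugClaim] = []
    for agent in agents:
        route = AGENT_ROUTES[agent]
        cadence = cfg.admin_supply_days if route == "parenteral" else cfg.oral_supply_days
        day = start
        while day <= end:
            supply = min(cadence, end - day + 1)
            claims.append(DrugClaim(_date(day), agent, supply, route, pid))
            day += cadence
    return claims


def _plant_comorbidities(
    rng: np.random.Generator, pid: str, stratum: str, index_day: int, cfg: SimulationConfig
) -> list[DiagnosisEvent]:
    code_map = default_code_map()
    events: list[DiagnosisEvent] = []
    prevalence = cfg.comorbidity_prevalence.get(stratum, {})
    for cond in sorted(prevalence):
        if cond not in code_map.category_codes:
            continue
        if rng.random() < prevalence[cond]:
            offset = int(rng.integers(1, _STUDY_COMORBIDITY_WINDOW + 1))
            code = sorted(code_map.category_codes[cond])[0]
            events.append(DiagnosisEvent(_date(index_day - offset), code, pid))
    return events


def _apply_violation(
    rng: np.random.Generator,
    pid: str,
    claims: list[DrugClaim],
    planned: list[dict],
    cfg: SimulationConfig,
) -> list[DrugClaim]:
    """Inject a rule-violating pattern into one planned line."""
    if not planned:
        return claims
    target = planned[int(rng.integers(0, len(planned)))]
    s, e = target["start"], target["end"]
    if rng.random() < 0.5 and e - s > 120:
        # deliberate >=60-day intra-line gap: push the back half of the
        # line's claims (and their coverage) out by 75 days
        cut = (s + e) // 2
        shift = 75
        out = []
        for c in claims:
            if s <= _days(c.date) <= e and _days(c.date) >= cut:
                out.append(DrugClaim(c.date + timedelta(days=shift), c.agent,
                                     c.days_supply, c.route, c.patient_id))
            else:
                out.append(c)
        return out
    # late add-on: a novel agent outside the regimen appears mid-line
    addon = "pomalidomide" if "pomalidomide" not in target["agents"] else "ixazomib"
    day = s + 75
    extra = []
    while day <= max(e, s + 105):
        extra.append(DrugClaim(_date(day), addon, cfg.oral_supply_days, "oral", pid))
        day += cfg.oral_supply_days
    return claims + extra


def generate_population(config: SimulationConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patient records.

    Raises ``pydantic.ValidationError`` naming the offending field when the
    config violates its invariants (validation happens at construction).
    """
    rng = np.random.default_rng(config.seed)
    code_map = default_code_map()
    mm_code = sorted(code_map.category_codes["multiple_myeloma"])[0]
    prior_code = sorted(code_map.category_codes["other_malignancy"])[0]

    lo, hi = config.index_date_range
    lo_d, hi_d = _days(lo), _days(hi)
    patients: list[PatientRecord] = []

    for i in range(config.n_patients):
        pid = f"S{config.seed}-{i:06d}"
        stratum = "transplant" if rng.random() < config.p_transplant else "non_transplant"
        journey = config.journeys[stratum]

        age_mu, age_sd = config.age_mean_sd[stratum]
        age = float(rng.normal(age_mu, age_sd))
        while not 20.0 <= age <= 100.0:
            age = float(rng.normal(age_mu, age_sd))
        age = int(age)
        sex = "male" if rng.random() < config.male_fraction[stratum] else "female"
        race = _choice(rng, config.race_mix)
        source_kind = "emr" if rng.random() < config.emr_fraction else "claims"

        index_day = int(rng.integers(lo_d, hi_d + 1))
        birth_year = _date(index_day).year - age

        diagnoses = [DiagnosisEvent(_date(index_day), mm_code, pid)]
        diagnoses += _plant_comorbidities(rng, pid, stratum, index_day, config)
        prior_malignancy = rng.random() < config.prior_malignancy_rate
        if prior_malignancy:
            offset = int(rng.integers(30, 365))
            diagnoses.append(DiagnosisEvent(_date(index_day - offset), prior_code, pid))

        # ---- journey: draw lines until censoring or death ------------------
        planned: list[dict] = []
        outcomes: list[str] = []
        cursor = index_day + int(rng.integers(7, 61))
        k = 0
        while k < config.max_lines:
            mu, sigma = journey.lognormal_params(k)
            dur = _duration_days(rng, mu, sigma)
            category = _choice(rng, config.regimen_mix[stratum])
            agents = _draw_agents(rng, category)
            planned.append({"start": cursor, "end": cursor + dur - 1,
                            "agents": frozenset(agents), "category": category})
            u = rng.random()
            cont = journey.prob("continuation", k)
            die = journey.prob("death", k)
            if u < cont:
                outcome = "continue"
            elif u < cont + die:
                outcome = "death"
            else:
                outcome = "censor"
            if outcome == "continue" and k + 1 >= config.max_lines:
                outcome = "censor"  # journey truncated at the line cap
            outcomes.append(outcome)
            if outcome != "continue":
                break
            cursor = planned[-1]["end"] + _gap_days(rng, config)
            k += 1

        # ---- transplant: ASCT placement and consolidation ------------------
        procedures: list[ProcedureEvent] = []
        asct_day: Optional[int] = None
        consolidation = False
        induction_line = None
        if stratum == "transplant" and config.max_asct_per_patient > 0:
            n_lines = len(planned)
            if n_lines == 1:
                frontline = True
            else:
                p1 = min(1.0, max(0.0, (config.frontline_induction_fraction
                                        - (1 - config.journeys[stratum].continuation[0]))
                                  / max(config.journeys[stratum].continuation[0], 1e-12)))
                frontline = rng.random() < p1
            if frontline:
                induction_line = 0
                e1 = planned[0]["end"]
                asct_day = e1 + int(rng.integers(14, 46))
                consolidation = rng.random() < config.consolidation_fraction
                if consolidation:
                    c_start = asct_day + int(rng.integers(7, 61))
                    c_dur = int(rng.integers(30, 121))
                    c_end = c_start + c_dur - 1
                    planned[0]["consolidation"] = (c_start, c_end)
                    planned[0]["end_final"] = c_end
                    shift_from = c_end
                else:
                    shift_from = asct_day
                # subsequent treatment must not be mistakable for consolidation
                if n_lines > 1:
                    min_next = max(asct_day + 123, shift_from + 61)
                    delta = min_next - planned[1]["start"]
                    if delta > 0:
                        for line in planned[1:]:
                            line["start"] += delta
                            line["end"] += delta
            else:
                induction_line = 1
                asct_day = planned[1]["start"] + int(rng.integers(1, 15))
                if n_lines > 2 and planned[2]["start"] <= asct_day + 122:
                    delta = asct_day + 123 - planned[2]["start"]
                    for line in planned[2:]:
                        line["start"] += delta
                        line["end"] += delta
            procedures.append(ProcedureEvent(_date(asct_day), "ASCT", pid))

        # ---- claims emission ----------------------------------------------
        claims: list[DrugClaim] = []
        for line in planned:
            claims += _emit_line_claims(pid, tuple(sorted(line["agents"])),
                                        line["start"], line["end"], config)
            if "consolidation" in line:
                cs, ce = line["consolidation"]
                claims += _emit_line_claims(pid, tuple(sorted(line["agents"])),
                                            cs, ce, config)

        violated = rng.random() < config.violation_fraction
        if violated:
            claims = _apply_violation(rng, pid, claims, planned, config)

        # ---- death and coverage -------------------------------------------
        event_days = [index_day] + [_days(c.date) for c in claims]
        event_days += [_days(p.date) for p in procedures]
        last_activity = max(event_days)
        death_day: Optional[int] = None
        if outcomes and outcomes[-1] == "death":
            death_day = last_activity + int(rng.integers(1, 31))

        cov_start = index_day - 365 - int(rng.integers(0, 366))
        if death_day is not None:
            cov_end = death_day + int(rng.integers(0, 121))
        else:
            cov_end = last_activity + int(rng.integers(90, 366))
        if config.coverage_censor_rate > 0:
            t_years = float(rng.exponential(1.0 / config.coverage_censor_rate))
            cov_end = min(cov_end, index_day + int(t_years * 365.25))
            cov_end = max(cov_end, cov_start)
        coverage = [
            CoverageInterval(_date(cov_start), _date(cov_end), "medical", pid),
            CoverageInterval(_date(cov_start), _date(cov_end), "pharmacy", pid),
        ]

        record = PatientRecord(
            patient_id=pid,
            birth_year=birth_year,
            sex=sex,
            race=race,
            death_date=_date(death_day) if death_day is not None else None,
            source_kind=source_kind,
            diagnosis_events=diagnoses,
            drug_claims=claims,
            procedure_events=procedures,
            coverage=coverage,
            truth={
                "stratum": stratum,
                # observed end of the final line extends to the death date:
                # follow-up (not a 60-day lapse) is what closes that line
                "planned_lines": [
                    (
                        _date(l["start"]),
                        _date(death_day) if (death_day is not None and j == len(planned) - 1)
                        else _date(l.get("end_final", l["end"])),
                        l["agents"],
                    )
                    for j, l in enumerate(planned)
                ],
                "outcomes": outcomes,
                "categories": [l["category"] for l in planned],
                "asct_day": _date(asct_day) if asct_day is not None else None,
                "induction_line": induction_line,
                "consolidation": consolidation,
                "violation": violated,
                "prior_malignancy": prior_malignancy,
            },
        )
        record.sort_events()
        patients.append(record)
    return patients
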
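"""Reading and writing the five delimited claim tables.

Layout (all CSV, UTF-8, ISO-8601 dates, documented column order):

* ``patients.csv``   — patient_id, birth_year, sex, race, death_date, source_kind
* ``diagnoses.csv``  — patient_id, date, code
* ``drug_claims.csv``— patient_id, date, agent, days_supply, route
* ``procedures.csv`` — patient_id, date, kind
* ``coverage.csv``   — patient_id, start, end, kind

plus ``simulation_config.json``, a sidecar echoing the resolved generator
config and seed when the tables were simulated.  Writing is canonical
(sorted rows), so write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import SimulationConfig
from .records import (
    CoverageInterval,
    DiagnosisEvent,
    DrugClaim,
    PatientRecord,
    ProcedureEvent,
)

TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_year", "sex", "race", "death_date", "source_kind"],
    "diagnoses": ["patient_id", "date", "code"],
    "drug_claims": ["patient_id", "date", "agent", "days_supply", "route"],
    "procedures": ["patient_id", "date", "kind"],
    "coverage": ["patient_id", "start", "end", "kind"],
}


def _iso(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def population_frames(population: Iterable[PatientRecord]) -> dict[str, pd.DataFrame]:
    """Flatten records into the five canonical tables (sorted rows)."""
    pts, dxs, rxs, prs, cov = [], [], [], [], []
    for p in population:
        pts.append((p.patient_id, p.birth_year, p.sex or "", p.race,
                    _iso(p.death_date), p.source_kind))
        for e in p.diagnosis_events:
            dxs.append((p.patient_id, e.date.isoformat(), e.code))
        for c in p.drug_claims:
            rxs.append((p.patient_id, c.date.isoformat(), c.agent,
                        "" if c.days_supply is None else c.days_supply, c.route))
        for pr in p.procedure_events:
            prs.append((p.patient_id, pr.date.isoformat(), pr.kind))
        for ci in p.coverage:
            cov.append((p.patient_id, ci.start.isoformat(), ci.end.isoformat(), ci.kind))
    frames = {
        "patients": pd.DataFrame(pts, columns=TABLE_COLUMNS["patients"]),
        "diagnoses": pd.DataFrame(dxs, columns=TABLE_COLUMNS["diagnoses"]),
        "drug_claims": pd.DataFrame(rxs, columns=TABLE_COLUMNS["drug_claims"]),
        "procedures": pd.DataFrame(prs, columns=TABLE_COLUMNS["procedures"]),
        "coverage": pd.DataFrame(cov, columns=TABLE_COLUMNS["coverage"]),
    }
    for name, df in frames.items():
        frames[name] = df.sort_values(TABLE_COLUMNS[name], kind="mergesort").reset_index(drop=True)
    return frames


def write_claims_tables(
    population: Iterable[PatientRecord],
    directory: str | Path,
    config: Optional[SimulationConfig] = None,
) -> list[Path]:
    """Write the five tables (and the config sidecar) under *directory*."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in population_frames(population).items():
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False, lineterminator="\n")
            written.append(path)
        if config is not None:
            sidecar = directory / "simulation_config.json"
            sidecar.write_text(json.dumps(config.model_dump(mode="json"),
                                          indent=2, sort_keys=True) + "\n")
            written.append(sidecar)
        return written
    except OSError as exc:
        raise OSError(f"failed writing claims tables under {directory}: {exc}") from exc


def _parse_date(s: str) -> Optional[date]:
    return date.fromisoformat(s) if s else None


def read_claims_tables(directory: str | Path) -> list[PatientRecord]:
    """Load the five tables back into :class:`PatientRecord` objects.

    Raises ``FileNotFoundError`` naming the first missing table.
    """
    directory = Path(directory)
    frames = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required claims table missing: {path}")
        frames[name] = pd.read_csv(path, dtype=str, keep_default_na=False)

    records: dict[str, PatientRecord] = {}
    for row in frames["patients"].itertuples(index=False):
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            birth_year=int(row.birth_year),
            sex=row.sex or None,
            race=row.race,
            death_date=_parse_date(row.death_date),
            source_kind=row.source_kind,
        )
    for row in frames["diagnoses"].itertuples(index=False):
        records[row.patient_id].diagnosis_events.append(
            DiagnosisEvent(date.fromisoformat(row.date), row.code, row.patient_id))
    for row in frames["drug_claims"].itertuples(index=False):
        records[row.patient_id].drug_claims.append(
            DrugClaim(date.fromisoformat(row.date), row.agent,
                      int(row.days_supply) if row.days_supply else None,
                      row.route, row.patient_id))
    for row in frames["procedures"].itertuples(index=False):
        records[row.patient_id].procedure_events.append(
            ProcedureEvent(date.fromisoformat(row.date), row.kind, row.patient_id))
    for row in frames["coverage"].itertuples(index=False):
        records[row.patient_id].coverage.append(
            CoverageInterval(date.fromisoformat(row.start),
                             date.fromisoformat(row.end), row.kind, row.patient_id))
    out = [records[pid] for pid in sorted(records)]
    for rec in out:
        rec.sort_events()
    return out
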
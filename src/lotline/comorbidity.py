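"""Charlson Comorbidity Index and named comorbidity flags.

The study evaluates comorbidity over a 180-day window ending the day before
an anchor date — either the index MM diagnosis or the start of the first
line of therapy, both of which are first-class anchors here.  The CCI uses
the classic 17-category weighting (1/2/3/6); multiple myeloma itself is a
Charlson malignancy and is excluded from the score by default so that the
index disease does not inflate every patient's score by 2.

Codes are resolved through a :class:`CodeMap` — a plain (category, code,
weight) table — because claims dialects (ICD-9/ICD-10, database-specific
grouping) vary; the default map ships representative ICD-10 codes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional

from .records import DiagnosisEvent

logger = logging.getLogger(__name__)

#: the eight named comorbidity flags reported by the study
FLAG_NAMES = (
    "cardiac_arrhythmia",
    "congestive_heart_failure",
    "hypertension_complicated",
    "hypertension_simple",
    "hepatic_disease",
    "pulmonary_circulation_disorders",
    "renal_impairment",
    "valvular_disease",
)

#: flags folded into the single cardiovascular covariate for modelling
CARDIOVASCULAR_COMPOSITE_FLAGS = (
    "cardiac_arrhythmia",
    "congestive_heart_failure",
    "hypertension_complicated",
    "valvular_disease",
)

#: flag -> contributing condition categories
FLAG_CATEGORIES: dict[str, tuple[str, ...]] = {
    "cardiac_arrhythmia": ("cardiac_arrhythmia",),
    "congestive_heart_failure": ("congestive_heart_failure",),
    "hypertension_complicated": ("hypertension_complicated",),
    "hypertension_simple": ("hypertension_simple",),
    "hepatic_disease": ("hepatic_disease", "severe_liver_disease"),
    "pulmonary_circulation_disorders": ("pulmonary_circulation",),
    "renal_impairment": ("renal_disease",),
    "valvular_disease": ("valvular_disease",),
}

# classic 17-category Charlson weights (category names are this package's)
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular": 1,
    "cerebrovascular": 1,
    "dementia": 1,
    "copd": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer": 1,
    "hepatic_disease": 1,  # mild liver disease
    "diabetes": 1,
    "diabetes_complicated": 2,
    "hemiplegia": 2,
    "renal_disease": 2,
    "multiple_myeloma": 2,  # Charlson malignancy; excluded from CCI by default
    "other_malignancy": 2,
    "severe_liver_disease": 3,
    "metastatic_tumor": 6,
    "aids": 6,
}

#: (severe category, mild category) — the mild member is suppressed when both present
HIERARCHY: tuple[tuple[str, str], ...] = (
    ("hypertension_complicated", "hypertension_simple"),
    ("severe_liver_disease", "hepatic_disease"),
    ("diabetes_complicated", "diabetes"),
    ("metastatic_tumor", "other_malignancy"),
)

_DEFAULT_CODES: dict[str, tuple[str, ...]] = {
    "multiple_myeloma": ("C90.00", "C90.01", "203.00"),
    "other_malignancy": ("C80.1", "C34.90", "C50.919", "199.1"),
    "cardiac_arrhythmia": ("I48.91", "I49.9", "427.31"),
    "congestive_heart_failure": ("I50.9", "I50.22", "428.0"),
    "hypertension_complicated": ("I11.0", "I12.0", "I13.0"),
    "hypertension_simple": ("I10", "401.9"),
    "hepatic_disease": ("K70.30", "K73.2", "571.5"),
    "severe_liver_disease": ("K72.10", "K76.6"),
    "pulmonary_circulation": ("I27.9", "I26.99", "416.9"),
    "renal_disease": ("N18.3", "N18.4", "N17.9", "585.9"),
    "valvular_disease": ("I34.0", "I35.0", "424.0"),
    "myocardial_infarction": ("I21.9", "I25.2"),
    "peripheral_vascular": ("I73.9",),
    "cerebrovascular": ("I63.9", "I69.30"),
    "dementia": ("F03.90", "G30.9"),
    "copd": ("J44.9", "J44.1"),
    "rheumatic_disease": ("M05.9", "M06.9"),
    "peptic_ulcer": ("K27.9",),
    "diabetes": ("E11.9", "E10.9"),
    "diabetes_complicated": ("E11.22", "E11.40"),
    "hemiplegia": ("G81.90",),
    "metastatic_tumor": ("C79.9",),
    "aids": ("B20",),
}


@dataclass(frozen=True)
class CodeMap:
    """Condition category -> diagnosis codes, plus Charlson weights.

    ``exclude_from_cci`` lists categories never counted toward the score
    (by default the index malignancy itself).
    """

    category_codes: dict[str, frozenset[str]]
    weights: dict[str, int]
    hierarchy: tuple[tuple[str, str], ...] = HIERARCHY
    exclude_from_cci: frozenset[str] = frozenset({"multiple_myeloma"})

    def category_of(self, code: str) -> Optional[str]:
        return self._code_index().get(code)

    def _code_index(self) -> dict[str, str]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {}
            for cat, codes in self.category_codes.items():
                for c in codes:
                    idx[c] = cat
            object.__setattr__(self, "_idx", idx)
        return idx

    def codes_for(self, category: str) -> frozenset[str]:
        return self.category_codes[category]


def default_code_map(exclude_mm_from_cci: bool = True) -> CodeMap:
    return CodeMap(
        category_codes={k: frozenset(v) for k, v in _DEFAULT_CODES.items()},
        weights=dict(CHARLSON_WEIGHTS),
        exclude_from_cci=frozenset({"multiple_myeloma"}) if exclude_mm_from_cci else frozenset(),
    )


def load_code_map(path: str | Path, **kwargs) -> CodeMap:
    """Read a delimited code map with columns category, code, weight (blank
    weight = not a Charlson category)."""
    cats: dict[str, set[str]] = {}
    weights: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cats.setdefault(row["category"], set()).add(row["code"])
            w = (row.get("weight") or "").strip()
            if w:
                weights[row["category"]] = int(w)
    return CodeMap(
        category_codes={k: frozenset(v) for k, v in cats.items()},
        weights=weights,
        **kwargs,
    )


def write_code_map(code_map: CodeMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "code", "weight"])
        for cat in sorted(code_map.category_codes):
            weight = code_map.weights.get(cat, "")
            for code in sorted(code_map.category_codes[cat]):
                w.writerow([cat, code, weight])


@dataclass
class ComorbidityProfile:
    patient_id: str
    window_anchor: str  # "index_diagnosis" | "first_lot_start"
    cci_score: int
    flags: dict[str, bool]
    unmapped_codes: int = 0

    @property
    def cardiovascular_composite(self) -> bool:
        return any(self.flags[f] for f in CARDIOVASCULAR_COMPOSITE_FLAGS)


def _categories_in_window(
    events: Iterable[DiagnosisEvent],
    anchor: date,
    window_days: int,
    code_map: CodeMap,
) -> tuple[set[str], int]:
    """Distinct condition categories with >=1 event in [anchor-window, anchor-1]."""
    lo = anchor - timedelta(days=window_days)
    present: set[str] = set()
    unmapped = 0
    for ev in events:
        if not (lo <= ev.date <= anchor - timedelta(days=1)):
            continue
        cat = code_map.category_of(ev.code)
        if cat is None:
            unmapped += 1
        else:
            present.add(cat)
    return present, unmapped


def _apply_hierarchy(present: set[str], code_map: CodeMap) -> set[str]:
    out = set(present)
    for severe, mild in code_map.hierarchy:
        if severe in out and mild in out:
            out.discard(mild)
    return out


def comorbidity_flags(
    events: Iterable[DiagnosisEvent],
    anchor: date,
    window_days: int = 180,
    code_map: Optional[CodeMap] = None,
    window_anchor: str = "index_diagnosis",
    patient_id: str = "",
) -> ComorbidityProfile:
    """Evaluate the eight named comorbidity flags and the CCI in one window.

    A flag is true iff at least one mapped diagnosis falls within the window
    (a single qualifying claim suffices; no confirmation rule).  Complicated
    hypertension suppresses simple hypertension for the same patient.
    """
    code_map = code_map or default_code_map()
    present, unmapped = _categories_in_window(events, anchor, window_days, code_map)
    if unmapped:
        logger.info("%d diagnosis codes not in the code map were ignored", unmapped)
    effective = _apply_hierarchy(present, code_map)
    flags = {
        flag: any(cat in effective for cat in FLAG_CATEGORIES[flag])
        for flag in FLAG_NAMES
    }
    score = _score(effective, code_map)
    return ComorbidityProfile(
        patient_id=patient_id,
        window_anchor=window_anchor,
        cci_score=score,
        flags=flags,
        unmapped_codes=unmapped,
    )


def _score(effective_categories: set[str], code_map: CodeMap) -> int:
    return sum(
        code_map.weights[cat]
        for cat in effective_categories
        if cat in code_map.weights and cat not in code_map.exclude_from_cci
    )


def cci_score(
    events: Iterable[DiagnosisEvent],
    anchor: date,
    window_days: int = 180,
    code_map: Optional[CodeMap] = None,
) -> int:
    """Charlson score: sum of weights over distinct in-window categories,
    each counted once, hierarchy applied (severe suppresses mild)."""
    code_map = code_map or default_code_map()
    present, _ = _categories_in_window(events, anchor, window_days, code_map)
    return _score(_apply_hierarchy(present, code_map), code_map)
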
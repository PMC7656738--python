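"""Validated configuration for every pipeline stage.

All knobs live here as pydantic models so that an invalid value fails fast
with the offending field named.  ``PipelineConfig`` aggregates the four
sections (``simulation:``, ``cohort:``, ``lot_rules:``, ``suppression:``)
and can be loaded from YAML or JSON.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# agent dictionary
# ---------------------------------------------------------------------------

#: Canonical anti-myeloma agents and their usual route.
AGENT_ROUTES: dict[str, str] = {
    "bortezomib": "parenteral",
    "carfilzomib": "parenteral",
    "ixazomib": "oral",
    "daratumumab": "parenteral",
    "elotuzumab": "parenteral",
    "lenalidomide": "oral",
    "thalidomide": "oral",
    "pomalidomide": "oral",
    "dexamethasone": "oral",
    "prednisone": "oral",
    "cyclophosphamide": "oral",
    "melphalan": "oral",
    "bendamustine": "parenteral",
    "doxorubicin": "parenteral",
}

KNOWN_AGENTS = frozenset(AGENT_ROUTES)
STEROID_AGENTS = frozenset({"dexamethasone", "prednisone"})
ALKYLATOR_AGENTS = frozenset({"cyclophosphamide", "melphalan", "bendamustine"})

STRATA = ("non_transplant", "transplant")


# ---------------------------------------------------------------------------
# line-of-therapy rules
# ---------------------------------------------------------------------------

class LotRules(BaseModel):
    """Business rules for segmenting drug claims into lines of therapy.

    The two clinically meaningful knobs are the 60-day discontinuation gap
    (a regimen agent off treatment that long ends the line) and the
    regimen-formation window (agents starting within it join the line's
    regimen instead of opening a new line).  Transplant consolidation is
    recognized within ``consolidation_window_days`` of ASCT when it persists
    ``consolidation_min_duration_days`` beyond it.
    """

    discontinuation_gap_days: int = 60
    regimen_formation_window_days: int = 60
    line_end_mode: str = "any_agent_discontinued"
    steroid_agents: frozenset[str] = STEROID_AGENTS
    steroids_trigger_new_line: bool = False
    consolidation_window_days: int = 122  # ~4 months
    consolidation_min_duration_days: int = 30  # ~1 month
    administration_default_supply_days: int = 7
    merge_gap_days: int = 0

    model_config = {"frozen": True}

    @field_validator(
        "discontinuation_gap_days",
        "regimen_formation_window_days",
        "consolidation_window_days",
        "consolidation_min_duration_days",
        "administration_default_supply_days",
        "merge_gap_days",
    )
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("day counts must be >= 0")
        return v

    @field_validator("line_end_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("any_agent_discontinued", "all_agents_discontinued"):
            raise ValueError("line_end_mode must be any_agent_discontinued or all_agents_discontinued")
        return v


# ---------------------------------------------------------------------------
# cohort criteria
# ---------------------------------------------------------------------------

class CohortCriteria(BaseModel):
    """Inclusion/exclusion rules applied in order by the cohort builder."""

    index_floor_date: date = date(2007, 1, 1)
    lookback_days: int = 365
    coverage_gap_days: int = 0  # permissible bridge between coverage intervals
    prior_malignancy_categories: tuple[str, ...] = ("other_malignancy",)

    model_config = {"frozen": True}


# ---------------------------------------------------------------------------
# suppression policy
# ---------------------------------------------------------------------------

class SuppressionPolicy(BaseModel):
    """CMS-style small-cell suppression: counts of 1-10 are never published."""

    suppress_min: int = 1
    suppress_max: int = 10
    secondary_suppression: bool = True
    replacement_token: str = "NR"

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _range(self) -> "SuppressionPolicy":
        if not (1 <= self.suppress_min <= self.suppress_max):
            raise ValueError("suppress range must satisfy 1 <= min <= max (0 is never suppressed)")
        return self


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class JourneyModel(BaseModel):
    """Per-line journey parameters for one transplant stratum.

    ``continuation[k]`` is the probability that a patient on line k+1 (0-based
    k) goes on to another line; ``death[k]`` the probability of death after
    that line; the remainder is censored treatment-free.  Line durations are
    log-normal in months, parameterized by the (mean, median) pair actually
    reported for real-world cohorts: sigma = sqrt(2 ln(mean/median)),
    mu = ln(median).  Lines beyond the vectors reuse the last entry.
    """

    continuation: tuple[float, ...]
    death: tuple[float, ...]
    duration_mean_months: tuple[float, ...]
    duration_median_months: tuple[float, ...]

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "JourneyModel":
        n = len(self.continuation)
        for name in ("death", "duration_mean_months", "duration_median_months"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have the same length as continuation")
        for name in ("continuation", "death"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        for c, d in zip(self.continuation, self.death):
            if c + d > 1.0 + 1e-12:
                raise ValueError("continuation + death must be <= 1 at every line")
        for m, med in zip(self.duration_mean_months, self.duration_median_months):
            if med <= 0 or m < med:
                raise ValueError("duration_mean_months must be >= duration_median_months > 0")
        return self

    def lognormal_params(self, line_index: int) -> tuple[float, float]:
        import math

        i = min(line_index, len(self.continuation) - 1)
        mean, med = self.duration_mean_months[i], self.duration_median_months[i]
        mu = math.log(med)
        sigma = math.sqrt(max(0.0, 2.0 * math.log(mean / med)))
        return mu, sigma

    def prob(self, vector: str, line_index: int) -> float:
        v = getattr(self, vector)
        return v[min(line_index, len(v) - 1)]


class GapModel(BaseModel):
    """Between-line treatment-free gap: min_days + LogNormal(log_mu, log_sigma) days."""

    min_days: int = 61
    log_mu: float = 3.5
    log_sigma: float = 0.6

    model_config = {"frozen": True}


def _default_journeys() -> dict[str, JourneyModel]:
    return {
        "non_transplant": JourneyModel(
            continuation=(0.431, 0.545, 0.573, 0.574, 0.580),
            death=(0.129, 0.122, 0.123, 0.123, 0.123),
            duration_mean_months=(6.9, 7.5, 6.5, 5.7, 5.5),
            duration_median_months=(3.6, 4.1, 3.7, 3.4, 3.2),
        ),
        "transplant": JourneyModel(
            continuation=(0.790, 0.692, 0.631, 0.648, 0.629),
            death=(0.013, 0.027, 0.042, 0.063, 0.079),
            duration_mean_months=(6.3, 6.1, 7.4, 6.6, 5.6),
            duration_median_months=(4.2, 2.7, 3.6, 3.4, 3.3),
        ),
    }


def _default_regimen_mix() -> dict[str, dict[str, float]]:
    # Frontline mixes: doublets dominate for non-transplant patients
    # (Vd 20%, Rd 19%), VRd dominates induction (33%); the remaining mass is
    # spread over the usual bortezomib-containing and legacy regimens.
    return {
        "non_transplant": {
            "Vd": 0.20, "Rd": 0.19, "VRd": 0.11, "V/alkylator": 0.09,
            "V": 0.06, "R": 0.05, "T": 0.02, "other": 0.28,
        },
        "transplant": {
            "VRd": 0.33, "Vd": 0.10, "Rd": 0.07, "V/alkylator": 0.14,
            "V": 0.02, "R": 0.02, "T": 0.01, "other": 0.31,
        },
    }


def _default_prevalence() -> dict[str, dict[str, float]]:
    # Pre-treatment 180-day prevalences by stratum; the eight named
    # conditions use the overall real-world rates, the remaining Charlson
    # categories carry modest realistic rates.
    return {
        "non_transplant": {
            "cardiac_arrhythmia": 0.196, "congestive_heart_failure": 0.135,
            "hypertension_complicated": 0.169, "hypertension_simple": 0.530,
            "hepatic_disease": 0.044, "pulmonary_circulation": 0.047,
            "renal_disease": 0.241, "valvular_disease": 0.102,
            "diabetes": 0.18, "copd": 0.12, "cerebrovascular": 0.08,
            "myocardial_infarction": 0.05, "peripheral_vascular": 0.07,
            "dementia": 0.04, "rheumatic_disease": 0.03, "peptic_ulcer": 0.02,
        },
        "transplant": {
            "cardiac_arrhythmia": 0.106, "congestive_heart_failure": 0.042,
            "hypertension_complicated": 0.094, "hypertension_simple": 0.476,
            "hepatic_disease": 0.055, "pulmonary_circulation": 0.020,
            "renal_disease": 0.170, "valvular_disease": 0.057,
            "diabetes": 0.10, "copd": 0.05, "cerebrovascular": 0.03,
            "myocardial_infarction": 0.02, "peripheral_vascular": 0.03,
            "dementia": 0.005, "rheumatic_disease": 0.02, "peptic_ulcer": 0.01,
        },
    }


class SimulationConfig(BaseModel):
    """Generative parameters for the synthetic claims population.

    Defaults emulate a newly-diagnosed multiple-myeloma claims cohort:
    index diagnoses from 2007 on, ~11% of patients transplanted, per-line
    continuation/death probabilities and log-normal durations matching
    published real-world attrition tables, and 180-day pre-index comorbidity
    prevalences by stratum.  Identical seed + config yields byte-identical
    output tables.
    """

    n_patients: int = 1000
    index_date_range: tuple[date, date] = (date(2007, 1, 1), date(2015, 12, 31))
    p_transplant: float = 0.111
    journeys: dict[str, JourneyModel] = Field(default_factory=_default_journeys)
    gap_model: GapModel = Field(default_factory=GapModel)
    regimen_mix: dict[str, dict[str, float]] = Field(default_factory=_default_regimen_mix)
    comorbidity_prevalence: dict[str, dict[str, float]] = Field(default_factory=_default_prevalence)
    frontline_induction_fraction: float = 0.609
    consolidation_fraction: float = 0.111
    violation_fraction: float = 0.05
    coverage_censor_rate: float = 0.0  # per-year hazard of eligibility loss
    prior_malignancy_rate: float = 0.02
    emr_fraction: float = 0.0
    age_mean_sd: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"non_transplant": (72.0, 10.4), "transplant": (65.0, 8.7)}
    )
    male_fraction: dict[str, float] = Field(
        default_factory=lambda: {"non_transplant": 0.503, "transplant": 0.563}
    )
    race_mix: dict[str, float] = Field(
        default_factory=lambda: {"white": 0.58, "black": 0.13, "asian": 0.02,
                                 "hispanic": 0.01, "unknown_other": 0.26}
    )
    oral_supply_days: int = 30
    admin_supply_days: int = 7
    max_lines: int = 8
    max_asct_per_patient: int = 1
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("n_patients")
    @classmethod
    def _n(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_patients must be >= 0")
        return v

    @field_validator("p_transplant", "frontline_induction_fraction",
                     "consolidation_fraction", "violation_fraction",
                     "prior_malignancy_rate", "emr_fraction")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("must be a probability in [0, 1]")
        return v

    @field_validator("coverage_censor_rate")
    @classmethod
    def _rate(cls, v: float) -> float:
        if v < 0:
            raise ValueError("coverage_censor_rate must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.index_date_range
        if lo > hi:
            raise ValueError("index_date_range must be ordered (start <= end)")
        for stratum in STRATA:
            if stratum not in self.journeys:
                raise ValueError(f"journeys missing stratum {stratum!r}")
            if stratum not in self.regimen_mix:
                raise ValueError(f"regimen_mix missing stratum {stratum!r}")
            total = sum(self.regimen_mix[stratum].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"regimen_mix[{stratum!r}] must sum to 1 (got {total})")
            for p in self.regimen_mix[stratum].values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"regimen_mix[{stratum!r}] entries must be in [0, 1]")
        for stratum, prev in self.comorbidity_prevalence.items():
            for cond, p in prev.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"comorbidity_prevalence[{stratum!r}][{cond!r}] must be in [0, 1]")
        if abs(sum(self.race_mix.values()) - 1.0) > 1e-9:
            raise ValueError("race_mix must sum to 1")
        return self


# ---------------------------------------------------------------------------
# aggregate pipeline config
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    cohort: CohortCriteria = Field(default_factory=CohortCriteria)
    lot_rules: LotRules = Field(default_factory=LotRules)
    suppression: SuppressionPolicy = Field(default_factory=SuppressionPolicy)

    model_config = {"frozen": True}

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML (or JSON) file."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    return PipelineConfig.model_validate(data)
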
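"""Frontline regimen classification.

Maps a line's agent set onto the presentation categories used for
frontline multiple-myeloma regimens: Vd, Rd, VRd, V/alkylator, V, R, T and
``other``.  The rule list is ordered data (first match wins), so alternative
bucketings are a configuration change, not a code change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .config import ALKYLATOR_AGENTS, KNOWN_AGENTS

logger = logging.getLogger(__name__)

REGIMEN_LABELS = ("Vd", "Rd", "VRd", "V/alkylator", "V", "R", "T", "other")


@dataclass(frozen=True)
class RegimenRule:
    """One ordered classification rule.

    ``required`` agents must all be present; ``any_of`` (if nonempty) demands
    at least one member; ``optional`` agents may also appear.  No agent
    outside required|any_of|optional may be present (exact-style matching, so
    a triplet plus an extra novel agent falls through to ``other``).
    """

    label: str
    rule_id: str
    required: frozenset[str]
    any_of: frozenset[str] = frozenset()
    optional: frozenset[str] = frozenset()

    def matches(self, agents: frozenset[str]) -> bool:
        if not self.required <= agents:
            return False
        if self.any_of and not (self.any_of & agents):
            return False
        allowed = self.required | self.any_of | self.optional
        return agents <= allowed


def default_rules() -> list[RegimenRule]:
    V, R, T, d = "bortezomib", "lenalidomide", "thalidomide", "dexamethasone"
    return [
        RegimenRule("VRd", "vrd_exact", frozenset({V, R, d})),
        RegimenRule("Vd", "vd_exact", frozenset({V, d})),
        RegimenRule("Rd", "rd_exact", frozenset({R, d})),
        RegimenRule("V/alkylator", "v_alkylator", frozenset({V}),
                    any_of=ALKYLATOR_AGENTS, optional=frozenset({d})),
        RegimenRule("V", "v_mono", frozenset({V})),
        RegimenRule("R", "r_mono", frozenset({R})),
        RegimenRule("T", "t_mono", frozenset({T})),
    ]


@dataclass(frozen=True)
class RegimenCategory:
    label: str
    matched_rule: str


def classify_regimen(
    agents: Iterable[str], rules: Optional[list[RegimenRule]] = None
) -> RegimenCategory:
    """Classify a nonempty agent set into exactly one regimen category.

    First match on the ordered rule list wins; anything unmatched is
    ``other``.  Unknown agents are tolerated (warned once per call) and the
    set containing them classifies as ``other`` unless a rule happens to
    match the known subset exactly — it will not, because exact matching
    forbids extraneous members.
    """
    agent_set = frozenset(agents)
    if not agent_set:
        raise ValueError("agent set must be nonempty")
    unknown = agent_set - KNOWN_AGENTS
    if unknown:
        logger.warning("unknown agents in regimen: %s", sorted(unknown))
    for rule in rules if rules is not None else default_rules():
        if rule.matches(agent_set):
            return RegimenCategory(rule.label, rule.rule_id)
    return RegimenCategory("other", "fallback_other")


# ---------------------------------------------------------------------------
# concrete agent sets per category, used by the synthetic generator
# ---------------------------------------------------------------------------

#: category -> [(agent tuple, weight)]; weights normalize within a category.
CATEGORY_AGENT_SETS: dict[str, list[tuple[tuple[str, ...], float]]] = {
    "Vd": [(("bortezomib", "dexamethasone"), 1.0)],
    "Rd": [(("lenalidomide", "dexamethasone"), 1.0)],
    "VRd": [(("bortezomib", "lenalidomide", "dexamethasone"), 1.0)],
    "V/alkylator": [
        (("bortezomib", "cyclophosphamide", "dexamethasone"), 0.7),
        (("bortezomib", "melphalan", "dexamethasone"), 0.3),
    ],
    "V": [(("bortezomib",), 1.0)],
    "R": [(("lenalidomide",), 1.0)],
    "T": [(("thalidomide",), 1.0)],
    "other": [
        (("thalidomide", "dexamethasone"), 0.30),
        (("bortezomib", "lenalidomide"), 0.20),
        (("cyclophosphamide", "dexamethasone"), 0.20),
        (("daratumumab", "bortezomib", "dexamethasone"), 0.15),
        (("carfilzomib", "lenalidomide", "dexamethasone"), 0.15),
    ],
}
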
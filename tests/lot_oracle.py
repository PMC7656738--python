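"""Independent brute-force day-by-day oracle for line-of-therapy rules.

Scans calendar days one at a time and applies the segmentation rules
literally: a line starts at the first administration at/after the cursor;
agents first administered within the formation window join the regimen;
each subsequent day either triggers a new-agent event (first administration
of a non-regimen, non-exempt agent), completes a discontinuation gap for a
regimen agent (or for the union coverage in all-agents mode), or runs into
the end of follow-up.  Entirely mask-based — shares no code with the
package's interval implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OracleClaim:
    day: int
    agent: str
    supply: int | None = None  # None = administration without supply
    route: str = "oral"


@dataclass(frozen=True)
class OracleLine:
    start: int
    end: int
    regimen: frozenset
    reason: str


def simulate_lines(
    claims,
    followup_end: int,
    gap_days: int = 60,
    formation_window: int = 60,
    steroid_agents=frozenset({"dexamethasone", "prednisone"}),
    steroids_exempt: bool = True,
    all_agents_mode: bool = False,
    admin_default_supply: int = 7,
    death_day=None,
) -> list[OracleLine]:
    claims = [c for c in claims if c.day <= followup_end]
    if not claims:
        return []
    horizon = followup_end + 1
    agents = sorted({c.agent for c in claims})

    def covered_mask(claim_subset, agent):
        mask = np.zeros(horizon, dtype=bool)
        for c in claim_subset:
            if c.agent != agent:
                continue
            supply = c.supply if c.supply is not None else admin_default_supply
            mask[c.day:min(c.day + supply, horizon)] = True
        return mask

    lines: list[OracleLine] = []
    cursor = min(c.day for c in claims)
    while True:
        sub = [c for c in claims if c.day >= cursor]
        if not sub:
            break
        line_start = min(c.day for c in sub)
        first_admin = {a: min(c.day for c in sub if c.agent == a)
                       for a in agents if any(c.agent == a for c in sub)}
        masks = {a: covered_mask(sub, a) for a in first_admin}
        regimen = {a for a, d in first_admin.items() if d <= line_start + formation_window}
        exempt = steroid_agents if steroids_exempt else frozenset()
        trigger = {a for a in regimen if a not in exempt} or set(regimen)
        if all_agents_mode:
            union = np.zeros(horizon, dtype=bool)
            for a in trigger:
                union |= masks[a]
            gap_masks = {"*union*": union}
        else:
            gap_masks = {a: masks[a] for a in sorted(trigger)}

        end = followup_end
        reason = "death" if (death_day is not None and followup_end >= death_day) else "followup_end"
        for t in range(line_start, followup_end + 1):
            # new agent administered after the formation window
            hit = [a for a, d in first_admin.items()
                   if d == t and t > line_start + formation_window and a not in exempt]
            if hit:
                end, reason = t - 1, "new_agent"
                break
            fired = False
            for a, mask in gap_masks.items():
                prior = mask[:t + 1]
                if not prior.any():
                    continue
                last_cov = int(np.nonzero(prior)[0][-1])
                if t - last_cov == gap_days:
                    end, reason, fired = last_cov, "gap", True
                    break
            if fired:
                break
        if steroids_exempt:
            for a in steroid_agents & set(first_admin):
                if line_start <= first_admin[a] <= end:
                    regimen.add(a)
        lines.append(OracleLine(line_start, max(end, line_start), frozenset(regimen), reason))
        cursor = end + 1
        if not any(c.day > end for c in claims):
            break
    return lines
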
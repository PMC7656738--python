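"""Exhaustive back-solver oracle for small-cell suppression safety.

Given one published row (a margin group after suppression) the solver
enumerates every non-negative integer fill of the masked cells that is
consistent with (a) the published margin, when visible, and (b) the
suppression policy itself — i.e. re-applying the policy to the candidate
row must reproduce exactly the observed mask pattern.  A masked cell is
"safe" when at least two distinct values survive for it.
"""

from __future__ import annotations

import itertools

import pandas as pd

from lotline import SuppressionPolicy, suppress_small_cells


def _compositions(total: int, parts: int, cap: int):
    """All tuples of `parts` ints >= 1 summing to `total` (each <= cap)."""
    if parts == 1:
        if 1 <= total <= cap:
            yield (total,)
        return
    for first in range(1, min(total - parts + 2, cap + 1)):
        for rest in _compositions(total - first, parts - 1, cap):
            yield (first,) + rest


def masked_cell_value_sets(
    published_row: dict,
    value_cols: list[str],
    policy: SuppressionPolicy,
    margin_col: str | None = None,
    cap: int = 400,
) -> dict[str, set[int]]:
    """Feasible values per masked cell of one published row."""
    token = policy.replacement_token
    masked = [c for c in value_cols if published_row[c] == token]
    if not masked:
        return {}
    known = {c: int(published_row[c]) for c in value_cols if published_row[c] != token}
    margin_masked = margin_col is not None and published_row[margin_col] == token

    candidates: dict[str, set[int]] = {c: set() for c in masked}
    if margin_col is not None and not margin_masked:
        totals = [int(published_row[margin_col]) - sum(known.values())]
    else:
        totals = range(len(masked), cap * len(masked) + 1)

    for total in totals:
        if total < len(masked):
            continue
        for fill in _compositions(total, len(masked), cap):
            row = dict(known)
            row.update(dict(zip(masked, fill)))
            trial = pd.DataFrame([{**{c: row[c] for c in value_cols},
                                   **({margin_col: sum(row.values())} if margin_col else {})}])
            redone = suppress_small_cells(trial, policy, margin_col=margin_col)
            pattern_ok = all(
                (redone.iloc[0][c] == token) == (published_row[c] == token)
                for c in value_cols
            )
            if margin_col is not None:
                pattern_ok &= (redone.iloc[0][margin_col] == token) == margin_masked
            if pattern_ok:
                for c, v in zip(masked, fill):
                    candidates[c].add(v)
        # unbounded-margin case: stop early once everything is proven safe
        if all(len(v) >= 2 for v in candidates.values()):
            break
    return candidates
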
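"""Attrition and disposition by line of therapy.

For each stratum and LOT k the table reports the number of patients who
reached the line, the attrition percent relative to the previous line,
the mutually exclusive dispositions after the line — death within
follow-up, no subsequent treatment in follow-up, or a subsequent line —
and the treatment-duration summary (mean, sample SD, median) in months.

Identities enforced (and fuzz-tested):

* n(LOT k) = subsequent_n(LOT k-1) for k >= 2,
* attrition_pct(LOT k) = 100 * (1 - n(k)/n(k-1)),
* deaths + no_subsequent + subsequent = n at every line.

A patient who starts line k+1 and later dies counts as subsequent
treatment at line k: the outcomes partition the line's cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import CohortMember, LineOfTherapy

__all__ = [
    "Disposition",
    "AttritionRow",
    "classify_disposition",
    "attrition_table",
    "attrition_table_from_counts",
    "duration_summary",
]

OUTCOMES = ("death", "no_subsequent_treatment", "subsequent_treatment")


@dataclass(frozen=True)
class Disposition:
    patient_id: str
    lot_number: int
    outcome: str


def classify_disposition(
    member: CohortMember, lines: Sequence[LineOfTherapy], k: int
) -> Disposition:
    """Outcome after line *k* (1-based) for a member who reached it.

    Subsequent treatment if a line k+1 exists; otherwise death if the death
    date lies within follow-up; otherwise no subsequent treatment (loss to
    follow-up or treatment-free censoring).
    """
    if len(lines) < k:
        raise ValueError(f"patient {member.patient_id} never reached LOT {k}")
    if len(lines) > k:
        outcome = "subsequent_treatment"
    elif member.death_date is not None and member.death_date <= member.followup_end:
        outcome = "death"
    else:
        outcome = "no_subsequent_treatment"
    return Disposition(member.patient_id, k, outcome)


def duration_summary(durations_months: Sequence[float]) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(mean, sample SD, median) of line durations in months.

    SD uses the n-1 denominator and is undefined (None) for n < 2; the
    median uses the midpoint convention for even n.  Empty input yields an
    all-None summary.
    """
    xs = sorted(durations_months)
    n = len(xs)
    if n == 0:
        return (None, None, None)
    mean = sum(xs) / n
    if n >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
    else:
        sd = None
    mid = n // 2
    median = xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0
    return (mean, sd, median)


@dataclass
class AttritionRow:
    stratum: str
    lot_number: int
    n: int
    attrition_pct: Optional[float]  # None for LOT1 and empty strata
    deaths_n: int
    no_subsequent_n: int
    subsequent_n: int
    duration_mean: Optional[float]
    duration_sd: Optional[float]
    duration_median: Optional[float]

    def pct(self, count: int) -> Optional[float]:
        return 100.0 * count / self.n if self.n else None


def attrition_pct(n_prev: int, n_curr: int) -> float:
    """Attrition percent entering line k: 100 * (1 - n_k / n_{k-1})."""
    return 100.0 * (1.0 - n_curr / n_prev)


def attrition_table(
    cohort: Sequence[CohortMember],
    lines: dict[str, Sequence[LineOfTherapy]],
    max_lot: int = 5,
) -> list[AttritionRow]:
    """Per-stratum, per-LOT cohort sizes, dispositions and durations."""
    rows: list[AttritionRow] = []
    for stratum in ("non_transplant", "transplant"):
        members = [m for m in cohort if m.transplant_status == stratum]
        n_prev: Optional[int] = None
        for k in range(1, max_lot + 1):
            reached = [m for m in members if len(lines.get(m.patient_id, ())) >= k]
            n = len(reached)
            counts = {o: 0 for o in OUTCOMES}
            durations = []
            for m in reached:
                ls = lines[m.patient_id]
                counts[classify_disposition(m, ls, k).outcome] += 1
                durations.append(ls[k - 1].duration_months)
            mean, sd, median = duration_summary(durations)
            rows.append(AttritionRow(
                stratum=stratum,
                lot_number=k,
                n=n,
                attrition_pct=attrition_pct(n_prev, n) if (k > 1 and n_prev) else None,
                deaths_n=counts["death"],
                no_subsequent_n=counts["no_subsequent_treatment"],
                subsequent_n=counts["subsequent_treatment"],
                duration_mean=mean,
                duration_sd=sd,
                duration_median=median,
            ))
            n_prev = n
    return rows


def attrition_table_from_counts(frequencies: Sequence[int], stratum: str = "") -> list[AttritionRow]:
    """Attrition rows from per-LOT frequency counts alone.

    Useful for checking the arithmetic identities of a published table: the
    subsequent count at line k is the frequency at line k+1 (0 at the last
    reported line), and only the attrition percentages are derivable.
    """
    rows = []
    for k, n in enumerate(frequencies, start=1):
        nxt = frequencies[k] if k < len(frequencies) else 0
        rows.append(AttritionRow(
            stratum=stratum, lot_number=k, n=n,
            attrition_pct=attrition_pct(frequencies[k - 2], n) if k > 1 else None,
            deaths_n=0, no_subsequent_n=n - nxt, subsequent_n=nxt,
            duration_mean=None, duration_sd=None, duration_median=None,
        ))
    return rows


def attrition_frame(rows: Sequence[AttritionRow], decimals: int = 1) -> pd.DataFrame:
    """Presentation-layer table: counts with percentages at one decimal."""
    def fmt_pct(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.{decimals}f}"

    recs = []
    for r in rows:
        recs.append({
            "stratum": r.stratum,
            "lot": r.lot_number,
            "n": r.n,
            "attrition_pct": fmt_pct(r.attrition_pct),
            "deaths_n": r.deaths_n,
            "deaths_pct": fmt_pct(r.pct(r.deaths_n)),
            "no_subsequent_n": r.no_subsequent_n,
            "no_subsequent_pct": fmt_pct(r.pct(r.no_subsequent_n)),
            "subsequent_n": r.subsequent_n,
            "subsequent_pct": fmt_pct(r.pct(r.subsequent_n)),
            "duration_mean": fmt_pct(r.duration_mean),
            "duration_sd": fmt_pct(r.duration_sd),
            "duration_median": fmt_pct(r.duration_median),
        })
    return pd.DataFrame(recs)


def plot_mean_duration(rows: Sequence[AttritionRow], path) -> None:
    """Bar chart of mean treatment duration by LOT and stratum (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    strata = sorted({r.stratum for r in rows})
    width = 0.38
    for j, stratum in enumerate(strata):
        sub = [r for r in rows if r.stratum == stratum and r.duration_mean is not None]
        ax.bar([r.lot_number + (j - 0.5) * width for r in sub],
               [r.duration_mean for r in sub], width=width, label=stratum)
    ax.set_xlabel("Line of therapy")
    ax.set_ylabel("Mean treatment duration (months)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
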
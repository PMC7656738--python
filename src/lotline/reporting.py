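"""Publication-style tables with CMS-style small-cell suppression, and the
end-to-end pipeline.

Counts of 1-10 are replaced by ``NR``; zero is never suppressed (an absent
category reveals nothing).  When exactly one cell in a margin group is
suppressed, its value could be back-solved from the published margin, so
the smallest other positive cell in the group is suppressed too; if the
group has no other positive cell, the group margin itself is masked.
Percentages tied to suppressed counts are masked at rendering.

``run_pipeline`` executes simulate -> cohort -> LOT -> comorbidity ->
attrition -> inference -> report and writes a deterministic bundle of CSV
tables plus a JSON manifest: the same seed and config reproduce the bundle
byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import attrition as attrition_mod
from . import inference as inference_mod
from .cohort import build_cohort
from .comorbidity import comorbidity_flags, default_code_map
from .config import PipelineConfig, SuppressionPolicy
from .io import read_claims_tables, write_claims_tables
from .simulate import generate_population

logger = logging.getLogger(__name__)

__all__ = ["suppress_small_cells", "run_pipeline"]


def _is_masked(value, token: str) -> bool:
    return isinstance(value, str) and value == token


def suppress_small_cells(
    table: pd.DataFrame,
    policy: Optional[SuppressionPolicy] = None,
    margin_col: Optional[str] = None,
) -> pd.DataFrame:
    """Mask small counts in a table whose rows are margin groups.

    Cells must be non-negative integers (or already-masked tokens, making
    the operation idempotent).  If ``margin_col`` is given it must equal the
    sum of the other cells in each row; inconsistent margins are a fatal
    validation error.
    """
    policy = policy or SuppressionPolicy()
    token = policy.replacement_token
    out = table.copy().astype(object)
    value_cols = [c for c in out.columns if c != margin_col]

    for idx in out.index:
        raw = {c: out.at[idx, c] for c in value_cols}
        numeric = {}
        for c, v in raw.items():
            if _is_masked(v, token):
                continue
            iv = int(v)
            if iv < 0:
                raise ValueError(f"cell [{idx}, {c}] is negative: {iv}")
            numeric[c] = iv
        if margin_col is not None and not any(_is_masked(v, token) for v in raw.values()):
            margin = int(out.at[idx, margin_col])
            if margin != sum(numeric.values()):
                raise ValueError(
                    f"inconsistent margin in row {idx!r}: {margin} != {sum(numeric.values())}")

        masked = {c for c, v in raw.items() if _is_masked(v, token)}
        for c, v in numeric.items():
            if policy.suppress_min <= v <= policy.suppress_max:
                masked.add(c)

        if policy.secondary_suppression and len(masked) == 1:
            partners = sorted(
                ((numeric[c], list(value_cols).index(c), c)
                 for c in numeric if c not in masked and numeric[c] > 0),
            )
            if partners:
                masked.add(partners[0][2])
            elif margin_col is not None:
                out.at[idx, margin_col] = token  # nothing to pair with: hide the margin

        for c in masked:
            out.at[idx, c] = token
    return out


def format_n_pct(n, total, token: str = "NR", decimals: int = 1) -> str:
    """Render ``n (pct)``, masking the percentage whenever the count is masked."""
    if _is_masked(n, token) or _is_masked(total, token):
        return token
    if not total:
        return f"{int(n)} (-)"
    return f"{int(n)} ({100.0 * int(n) / int(total):.{decimals}f})"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _demographics_counts(features: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Age-category counts by LOT use for one stratum (a Table-1-style block)."""
    sub = features[features["stratum"] == stratum]
    rows = []
    for label, grp in (
        (">1 LOT", sub[sub["received_subsequent"]]),
        ("only 1 LOT", sub[~sub["received_subsequent"]]),
    ):
        counts = grp["age_category"].value_counts()
        row = {"group": f"{stratum}:{label}"}
        for cat in ("<65", "65-74", "75-84", ">=85"):
            row[cat] = int(counts.get(cat, 0))
        row["total"] = int(len(grp))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    claims_dir: Optional[str | Path] = None,
    simulate: bool = True,
    seed: Optional[int] = None,
    max_lot: int = 5,
) -> dict:
    """Run the full analysis and write the report bundle under *out_dir*.

    Returns the manifest dict.  With ``simulate=True`` the synthetic
    generator provides the claims (written under ``out_dir/claims``);
    otherwise ``claims_dir`` must contain the five input tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation
    if seed is not None:
        sim_cfg = sim_cfg.model_copy(update={"seed": int(seed)})

    if simulate:
        logger.info("stage simulate: generating %d patients (seed %d)",
                    sim_cfg.n_patients, sim_cfg.seed)
        population = generate_population(sim_cfg)
        write_claims_tables(population, out_dir / "claims", sim_cfg)
    else:
        if claims_dir is None or not Path(claims_dir).is_dir():
            raise FileNotFoundError(f"claims directory not found: {claims_dir}")
        logger.info("stage load: reading claims from %s", claims_dir)
        population = read_claims_tables(claims_dir)

    logger.info("stage cohort: applying inclusion criteria")
    result = build_cohort(population, config.cohort, config.lot_rules)
    members, lines = result.members, result.lines
    pd.DataFrame(result.filter_log.to_rows()).to_csv(out_dir / "filter_log.csv", index=False)

    cohort_rows = [{
        "patient_id": m.patient_id,
        "index_diagnosis_date": m.index_diagnosis_date.isoformat(),
        "age_at_diagnosis": m.age_at_diagnosis,
        "age_category": m.age_category,
        "sex": m.sex,
        "race": m.race,
        "transplant_status": m.transplant_status,
        "followup_end": m.followup_end.isoformat(),
        "followup_months_from_first_lot": round(m.followup_months_from_first_lot, 4),
    } for m in members]
    pd.DataFrame(cohort_rows).to_csv(out_dir / "cohort.csv", index=False)

    logger.info("stage lot: writing %d patients' lines", len(lines))
    line_rows = []
    for pid in sorted(lines):
        for line in lines[pid]:
            line_rows.append({
                "patient_id": pid,
                "lot_number": line.lot_number,
                "start": line.start.isoformat(),
                "end": line.end.isoformat(),
                "agents": line.agents_label(),
                "category": line.regimen_category,
                "duration_months": round(line.duration_months, 4),
                "end_reason": line.end_reason,
                "induction": line.induction,
                "consolidation_present": line.consolidation_present,
            })
    pd.DataFrame(line_rows).to_csv(out_dir / "lines.csv", index=False)

    logger.info("stage comorbidity: scoring %d members", len(members))
    code_map = default_code_map()
    by_id = {p.patient_id: p for p in population}
    profiles = {}
    for m in members:
        profiles[m.patient_id] = comorbidity_flags(
            by_id[m.patient_id].diagnosis_events, m.index_diagnosis_date,
            code_map=code_map, window_anchor="index_diagnosis",
            patient_id=m.patient_id)
    prof_rows = [{
        "patient_id": pid,
        "cci_score": p.cci_score,
        "cardiovascular_composite": p.cardiovascular_composite,
        **{k: v for k, v in sorted(p.flags.items())},
    } for pid, p in sorted(profiles.items())]
    pd.DataFrame(prof_rows).to_csv(out_dir / "comorbidity.csv", index=False)

    logger.info("stage attrition")
    rows = attrition_mod.attrition_table(members, lines, max_lot=max_lot)
    attrition_mod.attrition_frame(rows).to_csv(out_dir / "attrition.csv", index=False)

    logger.info("stage inference")
    features = inference_mod.build_feature_table(members, lines, profiles)
    or_frames = []
    for stratum in ("non_transplant", "transplant"):
        for subset in ("overall", "6+", "12+", "24+"):
            sub = features[features["stratum"] == stratum]
            threshold = inference_mod.SUBSET_MONTHS[subset]
            avail = sub[sub["followup_months"] >= threshold] if threshold else sub
            if len(avail) == 0 or avail["received_subsequent"].nunique() < 2:
                continue
            spec = inference_mod.ModelSpec(subset=subset, stratum=stratum)
            results = inference_mod.fit_subsequent_treatment_model(features, spec)
            or_frames.append(inference_mod.odds_ratio_frame(
                results, stratum=stratum, subset=subset))
    if or_frames:
        pd.concat(or_frames, ignore_index=True).to_csv(
            out_dir / "predictors.csv", index=False, float_format="%.6g")

    logger.info("stage report: suppressed demographics")
    demo = pd.concat([_demographics_counts(features, s)
                      for s in ("non_transplant", "transplant")])
    suppressed = suppress_small_cells(demo, config.suppression, margin_col="total")
    suppressed.to_csv(out_dir / "demographics_suppressed.csv")

    (out_dir / "resolved_config.json").write_text(config.model_copy(
        update={"simulation": sim_cfg}).resolved_json() + "\n")
    manifest = {
        "seed": sim_cfg.seed,
        "n_patients_input": len(population),
        "n_cohort": len(members),
        "n_lines": sum(len(v) for v in lines.values()),
        "files": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
        "stages": ["simulate" if simulate else "load", "cohort", "lot",
                   "comorbidity", "attrition", "inference", "report"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
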
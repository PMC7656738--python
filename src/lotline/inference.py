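"""Group comparisons and logistic models of receiving a subsequent LOT.

``compare_groups`` contrasts patients with only one line against those with
more: chi-squared tests for categorical characteristics (the
Mantel-Haenszel / CMH general-association statistic when strata are
supplied; with a single stratum it reduces to the ordinary uncorrected
Pearson chi-squared) and two-sample t-tests for continuous ones (Welch by
default).

``fit_subsequent_treatment_model`` fits a maximum-likelihood logistic
regression of receiving LOT2+ on age category (reference 65-74), sex,
the cardiovascular composite, liver disease, pulmonary circulation
disorders and renal impairment, optionally restricted to patients with at
least 6/12/24 months of follow-up from first-LOT start (the censoring
sensitivity subsets).  Separation is flagged, never silently returned as
an infinite estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .comorbidity import ComorbidityProfile
from .records import AGE_CATEGORIES, CohortMember, LineOfTherapy

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "OddsRatioResult",
    "compare_groups",
    "fit_subsequent_treatment_model",
    "build_feature_table",
]

MODEL_COVARIATES = (
    "cardiovascular_disorders",
    "liver_disease",
    "pulmonary_circulation_disorders",
    "renal_impairment",
)

SUBSET_MONTHS = {"overall": 0.0, "6+": 6.0, "12+": 12.0, "24+": 24.0}


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def build_feature_table(
    members: Sequence[CohortMember],
    lines: dict[str, Sequence[LineOfTherapy]],
    profiles: dict[str, ComorbidityProfile],
) -> pd.DataFrame:
    """One row per cohort member with outcome, covariates and subset keys."""
    rows = []
    for m in members:
        prof = profiles[m.patient_id]
        rows.append({
            "patient_id": m.patient_id,
            "stratum": m.transplant_status,
            "received_subsequent": len(lines.get(m.patient_id, ())) >= 2,
            "age": m.age_at_diagnosis,
            "age_category": m.age_category,
            "male": m.sex == "male",
            "cci_score": prof.cci_score,
            "cardiovascular_disorders": prof.cardiovascular_composite,
            "liver_disease": prof.flags["hepatic_disease"],
            "pulmonary_circulation_disorders": prof.flags["pulmonary_circulation_disorders"],
            "renal_impairment": prof.flags["renal_impairment"],
            "followup_months": m.followup_months_from_first_lot,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    kind: str  # "categorical" | "continuous"
    statistic: Optional[float]
    p_value: Optional[float]
    n_group1: int
    n_group2: int
    note: str = ""


def _cmh_general_association(tables: list[np.ndarray]) -> tuple[float, float]:
    """CMH general-association statistic for a set of 2xJ stratum tables."""
    num = None
    var = None
    for t in tables:
        t = t.astype(float)
        n = t.sum()
        if n <= 1:
            continue
        row = t.sum(axis=1)
        col = t.sum(axis=0)
        expected = np.outer(row, col) / n
        obs = t[0, :-1]
        exp = expected[0, :-1]
        p_col = col / n
        v = (row[0] * row[1] / (n - 1)) * (np.diag(p_col[:-1]) - np.outer(p_col[:-1], p_col[:-1]))
        num = obs - exp if num is None else num + (obs - exp)
        var = v if var is None else var + v
    if num is None or var is None:
        return float("nan"), float("nan")
    stat = float(num @ np.linalg.pinv(var) @ num)
    df = len(num)
    return stat, float(stats.chi2.sf(stat, df))


def compare_groups(
    table: pd.DataFrame,
    group_col: str,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
    strata_col: Optional[str] = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Characteristic-by-characteristic comparison of two groups.

    Categorical variables get a chi-squared test: uncorrected Pearson when
    no ``strata_col`` is given (the single-stratum reduction of the
    Mantel-Haenszel statistic), otherwise the CMH general-association
    statistic across strata.  Continuous variables get a two-sample t-test
    (Welch unless ``welch=False``).  Zero-variance continuous variables are
    skipped with a notice.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"{group_col} must have exactly two levels, got {groups}")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    results: list[GroupTestResult] = []

    for var in categorical:
        if strata_col is None:
            ct = pd.crosstab(table[group_col], table[var])
            if ct.shape[1] < 2:
                results.append(GroupTestResult(var, "categorical", None, None,
                                               len(g1), len(g2), "single level; skipped"))
                continue
            stat, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
        else:
            tables = []
            for _, sub in table.groupby(strata_col):
                ct = pd.crosstab(sub[group_col], sub[var])
                ct = ct.reindex(index=groups, fill_value=0)
                if ct.shape[1] >= 2:
                    tables.append(ct.to_numpy())
            stat, p = _cmh_general_association(tables)
        results.append(GroupTestResult(var, "categorical", float(stat), float(p),
                                       len(g1), len(g2)))

    for var in continuous:
        x, y = g1[var].dropna(), g2[var].dropna()
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            results.append(GroupTestResult(var, "continuous", None, None,
                                           len(x), len(y), "zero variance; skipped"))
            continue
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
        results.append(GroupTestResult(var, "continuous", float(t), float(p),
                                       len(x), len(y)))

    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which subset/stratum to model; reference levels are fixed: age 65-74,
    female sex, each comorbidity absent."""

    subset: str = "overall"  # one of overall / 6+ / 12+ / 24+
    stratum: Optional[str] = None
    covariates: tuple[str, ...] = MODEL_COVARIATES
    include_age: bool = True
    include_sex: bool = True

    def __post_init__(self) -> None:
        if self.subset not in SUBSET_MONTHS:
            raise ValueError(f"subset must be one of {sorted(SUBSET_MONTHS)}")


@dataclass(frozen=True)
class OddsRatioResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    flagged: bool = False
    note: str = ""


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    y = df["received_subsequent"].astype(float)
    X = pd.DataFrame(index=df.index)
    if spec.include_age:
        for cat in AGE_CATEGORIES:
            if cat == "65-74":  # reference
                continue
            col = (df["age_category"] == cat).astype(float)
            if col.sum() > 0:
                X[f"age_{cat}"] = col
    if spec.include_sex:
        X["male"] = df["male"].astype(float)
    for cov in spec.covariates:
        X[cov] = df[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    return y, X


def fit_subsequent_treatment_model(
    features: pd.DataFrame, spec: Optional[ModelSpec] = None
) -> list[OddsRatioResult]:
    """ML logistic fit with Wald 95% CIs and p-values per non-reference term.

    The fit is deterministic given the data (Newton-Raphson, tolerance
    1e-8).  Perfect separation or non-convergence yields flagged results
    carrying the diagnostic instead of infinite estimates.
    """
    spec = spec or ModelSpec()
    df = features
    if spec.stratum is not None:
        df = df[df["stratum"] == spec.stratum]
    threshold = SUBSET_MONTHS[spec.subset]
    if threshold > 0:
        df = df[df["followup_months"] >= threshold]
    df = df.reset_index(drop=True)
    n = len(df)
    if n == 0 or df["received_subsequent"].nunique() < 2:
        raise ValueError("outcome must have both classes in the selected subset")

    y, X = _design(df, spec)
    terms = [c for c in X.columns if c != "const"]
    try:
        model = sm.Logit(y, X)
        fit = model.fit(disp=0, maxiter=100, tol=1e-8)
        if not fit.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("logistic fit did not converge")
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        flagged = bool((np.abs(params[terms]) > 15).any())
        note = "possible separation: |log-odds| > 15" if flagged else ""
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        logger.warning("logistic fit failed (%s); results flagged", exc)
        return [OddsRatioResult(t, float("nan"), float("nan"), float("nan"),
                                float("nan"), n, True, str(exc)) for t in terms]

    out = []
    for t in terms:
        beta, se = float(params[t]), float(bse[t])
        out.append(OddsRatioResult(
            term=t,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=float(pvals[t]),
            n=n,
            flagged=flagged,
            note=note,
        ))
    return out


def odds_ratio_frame(results: Sequence[OddsRatioResult], **extra) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    for k, v in extra.items():
        df[k] = v
    return df
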
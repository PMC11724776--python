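"""Cohort-level analyses relating adherence scores to diet and health.

Covers the epidemiological companion analyses of a screener validation:
food/nutrient means by score quartile with one-way ANOVA and a linear
p-for-trend, age- and sex-adjusted linear associations between the score
and cardiometabolic outcomes, HOMA-IR, sex-stratified descriptives, and a
sensitivity analysis that rebuilds the score without selected items.

Standard fits are delegated: OLS to statsmodels, ANOVA/t-tests/rank tests
to scipy.  No multiple-testing correction is applied (single pre-specified
model per outcome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
)
from . import scoring as scoring_mod

#: Denominator constant of the homeostatic model assessment when glucose is
#: in mg/dL and insulin in microU/mL.
HOMA_DENOMINATOR = 405.0

#: Outcomes whose distributions are summarised as median (P25-P75) with a
#: rank-based two-group test (right-skewed serum lipids); configurable.
DEFAULT_SKEWED_VARIABLES = ("total_chol", "hdl", "ldl", "tg")


@dataclass(frozen=True)
class AssociationResult:
    """Adjusted linear association of one outcome with the total score."""

    outcome: str
    beta: float  # per 1-point score increase, outcome units
    ci: tuple[float, float]
    p_value: float
    beta_standardized: float  # per SD of score, in outcome SDs
    n: int
    covariates: tuple[str, ...]


def homa_ir(glucose_mg_dl, insulin_microU_ml):
    """HOMA-IR = insulin [microU/mL] x glucose [mg/dL] / 405.

    Accepts scalars or arrays; glucose must be strictly positive and
    insulin non-negative.
    """
    glucose = np.asarray(glucose_mg_dl, dtype=float)
    insulin = np.asarray(insulin_microU_ml, dtype=float)
    if np.any(glucose <= 0):
        raise DomainError("glucose must be positive (mg/dL)")
    if np.any(insulin < 0):
        raise DomainError("insulin must be non-negative (microU/mL)")
    out = insulin * glucose / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def p_trend(values: Sequence[float], quartile_rank: Sequence[int]) -> tuple[float, float]:
    """Linear trend across ordered quartiles.

    Regresses the variable on the integer quartile rank (1-4) and returns
    (slope, two-sided p).
    """
    x = np.asarray(quartile_rank, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3 or np.unique(x).size < 2:
        raise InsufficientDataError("trend test needs >= 3 points in >= 2 groups")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def _mean_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    m = float(values.mean())
    if values.size < 2:
        return m, float("nan"), float("nan")
    sem = values.std(ddof=1) / np.sqrt(values.size)
    half = stats.t.ppf(1 - alpha / 2, values.size - 1) * sem
    return m, m - half, m + half


def quartile_summary(
    ffq_table: pd.DataFrame,
    scores: pd.DataFrame,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Mean (95% CI) of each variable by score quartile, with one-way
    ANOVA p and p-for-trend.

    ``scores`` must carry ``child_id`` and ``quartile`` (from
    :func:`med4child.scoring.score_table`); ``ffq_table`` carries the
    variables (g/day food groups or nutrient columns) per child.
    Zero-variance variables are retained with NaN p-values and flagged.
    """
    merged = scores[["child_id", "quartile"]].merge(ffq_table, on="child_id")
    present = [q for q in scoring_mod.QUARTILE_LABELS if (merged["quartile"] == q).any()]
    if len(present) < 2:
        raise InsufficientDataError("need >= 2 non-empty quartile groups")
    rank = merged["quartile"].map(
        {q: i + 1 for i, q in enumerate(scoring_mod.QUARTILE_LABELS)}
    )

    rows = []
    for var in variables:
        if var not in merged.columns:
            raise ConfigurationError(f"variable {var!r} not in FFQ table")
        y = merged[var].astype(float)
        row: dict = {"variable": var}
        groups = []
        for q in scoring_mod.QUARTILE_LABELS:
            vals = y[merged["quartile"] == q].to_numpy()
            if vals.size:
                m, lo, hi = _mean_ci(vals)
                groups.append(vals)
            else:
                m = lo = hi = float("nan")
            row[f"{q}_mean"], row[f"{q}_ci_low"], row[f"{q}_ci_high"] = m, lo, hi
            row[f"{q}_n"] = vals.size
        if np.isclose(y.var(ddof=0), 0.0):
            row["anova_p"] = float("nan")
            row["trend_slope"] = 0.0
            row["trend_p"] = float("nan")
            row["flag"] = "zero_variance"
        else:
            row["anova_p"] = float(stats.f_oneway(*groups).pvalue)
            row["trend_slope"], row["trend_p"] = p_trend(y, rank)
            row["flag"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def adjusted_association(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex"),
) -> AssociationResult:
    """OLS of one outcome on the total score, adjusted for covariates.

    Sex is encoded as a single indicator (girl = 1).  Reports the
    unstandardized beta per 1-point score increase with its 95% CI and p,
    plus a standardized beta (score and outcome both in SD units) in a
    separate field since the two scales must not be mixed.
    """
    merged = scores[["child_id", "total"]].merge(outcomes, on="child_id")
    cols = [outcome, "total", *covariates]
    missing = [c for c in cols if c not in merged.columns]
    if missing:
        raise ConfigurationError(f"missing columns {missing}")
    data = merged[cols].copy()
    if "sex" in covariates:
        data["sex"] = (
            merged["sex"].map({"girl": 1, "boy": 0})
            if merged["sex"].dtype == object
            else merged["sex"]
        )
    data = data.dropna()
    n = len(data)
    if n < max(10, len(covariates) + 3):
        raise InsufficientDataError(f"too few complete cases (n={n}) for {outcome}")

    X = sm.add_constant(data[["total", *covariates]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficiencyError(f"collinear design for outcome {outcome}")
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    beta = float(fit.params["total"])
    ci = tuple(float(v) for v in fit.conf_int().loc["total"])
    sd_score = float(data["total"].std(ddof=1))
    sd_out = float(data[outcome].std(ddof=1))
    beta_std = beta * sd_score / sd_out if sd_out > 0 else float("nan")
    return AssociationResult(
        outcome=outcome,
        beta=beta,
        ci=ci,
        p_value=float(fit.pvalues["total"]),
        beta_standardized=beta_std,
        n=n,
        covariates=tuple(covariates),
    )


def association_table(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_names: Sequence[str],
    covariates: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Adjusted associations for a list of outcomes, as a report table."""
    rows = []
    for name in outcome_names:
        res = adjusted_association(scores, outcomes, name, covariates)
        rows.append(
            {
                "outcome": res.outcome,
                "beta": res.beta,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "p_value": res.p_value,
                "beta_standardized": res.beta_standardized,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_exclude(
    items_to_drop: Iterable[int],
    questionnaire: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_names: Sequence[str],
    registry=None,
    covariates: Sequence[str] = ("age", "sex"),
    policy: str = "complete_case",
) -> pd.DataFrame:
    """Compare associations for the full score vs a reduced score that
    omits ``items_to_drop`` (e.g. the poorly agreeing unhealthy items).

    Returns one row per outcome with ``beta_full`` / ``beta_reduced``
    columns (plus CIs and p-values) side by side.
    """
    if registry is None:
        registry = scoring_mod.load_registry()
    drop = set(items_to_drop)
    all_items = {c.item_id for c in registry}
    if not drop <= all_items:
        raise ConfigurationError(f"unknown items to drop: {sorted(drop - all_items)}")
    kept = sorted(all_items - drop)
    if not kept:
        raise ConfigurationError("cannot drop all items: empty score")

    scored_full = scoring_mod.score_table(questionnaire, registry, policy=policy)
    scored_red = scoring_mod.score_table(
        questionnaire, registry, items_used=kept, policy=policy
    )
    full = association_table(scored_full, outcomes, outcome_names, covariates)
    red = association_table(scored_red, outcomes, outcome_names, covariates)
    out = full.merge(red, on="outcome", suffixes=("_full", "_reduced"))
    out.insert(1, "items_dropped", [",".join(map(str, sorted(drop)))] * len(out))
    return out


def describe_cohort(
    outcomes: pd.DataFrame,
    by: str | None = "sex",
    variables: Sequence[str] | None = None,
    skewed: Sequence[str] = DEFAULT_SKEWED_VARIABLES,
) -> pd.DataFrame:
    """Descriptive table, optionally compared between two groups.

    Variables flagged in ``skewed`` are summarised as median (P25-P75)
    and compared with the Mann-Whitney U test; all others as mean +/- SD
    with Welch's t-test.  Skewness routing is by configuration, not
    auto-detection, so output is deterministic.
    """
    if variables is None:
        variables = [
            c
            for c in outcomes.columns
            if c not in ("child_id", by) and pd.api.types.is_numeric_dtype(outcomes[c])
        ]
    groups = None
    if by is not None:
        levels = sorted(outcomes[by].dropna().unique().tolist())
        if len(levels) != 2:
            raise ConfigurationError(f"grouping column {by!r} must have 2 levels")
        groups = [outcomes[outcomes[by] == lev] for lev in levels]
        for g in groups:
            if len(g) < 2:
                raise InsufficientDataError("need n >= 2 per group")

    rows = []
    for var in variables:
        vals = outcomes[var].dropna().astype(float)
        row: dict = {"variable": var}
        if var in skewed:
            row["summary"] = (
                f"{vals.median():.1f}; "
                f"{vals.quantile(0.25):.1f}-{vals.quantile(0.75):.1f}"
            )
            row["kind"] = "median_iqr"
        else:
            row["summary"] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
            row["kind"] = "mean_sd"
        if groups is not None:
            g1 = groups[0][var].dropna().astype(float)
            g2 = groups[1][var].dropna().astype(float)
            if var in skewed:
                row["p_value"] = float(
                    stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue
                )
            else:
                row["p_value"] = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
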
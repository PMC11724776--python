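"""Inter-method agreement statistics for screener validation.

Per item, the administered screener and the FFQ-derived reference each
classify every child as scoring the point or not; agreement is summarised
by a 2x2 table, raw percent agreement (a+d)/n, and Cohen's kappa with a
large-sample (Fleiss-type) 95% confidence interval.  Kappa values are
interpreted on the conventional scale: <=0.20 weak, 0.21-0.40 fair,
0.41-0.60 moderate, 0.61-0.80 substantial, >0.80 almost perfect.
Total-score agreement uses the high-adherence dichotomy (>= 10 points),
and a Bland-Altman analysis (mean difference and limits of agreement of
administered minus FFQ-derived totals) quantifies score-level bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedKappaError,
)
from . import ffq as ffq_mod
from . import scoring as scoring_mod

KAPPA_BANDS = ("weak", "fair", "moderate", "substantial", "almost_perfect")
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one item (or the dichotomised total)."""

    key: str
    label: str
    a: int
    b: int
    c: int
    d: int
    n: int
    prop_method1: float
    prop_method2: float
    percent_agreement: float
    kappa: float  # NaN when undefined
    kappa_ci: tuple[float, float]  # (NaN, NaN) when undefined
    band: str | None
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement for paired scores."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    pairs: pd.DataFrame  # columns: mean, difference


def build_2x2(
    points1: Sequence[int], points2: Sequence[int]
) -> tuple[int, int, int, int]:
    """Cross-tabulate two paired binary vectors.

    Returns (a, b, c, d): a = both 1, b = method-1 only, c = method-2
    only, d = both 0.
    """
    v1 = np.asarray(points1)
    v2 = np.asarray(points2)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ConfigurationError("points1 and points2 must be equal-length vectors")
    for v in (v1, v2):
        if not np.isin(v, (0, 1)).all():
            raise ConfigurationError("inputs must be binary (0/1) with no missing")
    a = int(np.sum((v1 == 1) & (v2 == 1)))
    b = int(np.sum((v1 == 1) & (v2 == 0)))
    c = int(np.sum((v1 == 0) & (v2 == 1)))
    d = int(np.sum((v1 == 0) & (v2 == 0)))
    return a, b, c, d


def cohen_kappa(
    table: tuple[int, int, int, int]
) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa and asymptotic 95% CI for a 2x2 table (a, b, c, d).

    kappa = (Po - Pe) / (1 - Pe) with Po = (a+d)/n and Pe the sum of
    marginal products.  The CI uses the Fleiss-Cohen-Everitt large-sample
    variance, truncated to [-1, 1].  A degenerate table (Pe = 1, both
    methods constant and equal) raises :class:`UndefinedKappaError`.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ConfigurationError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise InsufficientDataError("empty 2x2 table")

    p = np.array([[a, b], [c, d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "expected agreement is 1 (both methods constant); kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt asymptotic variance of kappa-hat
    one_minus_k = 1.0 - kappa
    term_a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * one_minus_k) ** 2 for i in range(2)
    )
    term_b = one_minus_k**2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term_c = (kappa - pe * one_minus_k) ** 2
    var = (term_a + term_b - term_c) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    ci = (max(kappa - Z95 * se, -1.0), min(kappa + Z95 * se, 1.0))
    return kappa, ci


def kappa_band(kappa: float) -> str:
    """Interpretation band for a kappa value on the conventional scale."""
    if not -1.0 <= kappa <= 1.0:
        raise ConfigurationError(f"kappa {kappa} outside [-1, 1]")
    if kappa <= 0.20:
        return "weak"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost_perfect"


def agreement_from_table(
    key: str, label: str, table: tuple[int, int, int, int]
) -> AgreementResult:
    """Full agreement summary from a 2x2 table; degenerate tables are
    flagged rather than dropped."""
    a, b, c, d = table
    n = a + b + c + d
    if n == 0:
        raise InsufficientDataError("empty 2x2 table")
    try:
        kappa, ci = cohen_kappa(table)
        band = kappa_band(min(max(kappa, -1.0), 1.0))
        degenerate = False
    except UndefinedKappaError:
        kappa, ci, band, degenerate = float("nan"), (float("nan"), float("nan")), None, True
    return AgreementResult(
        key=key,
        label=label,
        a=a,
        b=b,
        c=c,
        d=d,
        n=n,
        prop_method1=(a + b) / n,
        prop_method2=(a + c) / n,
        percent_agreement=(a + d) / n,
        kappa=kappa,
        kappa_ci=ci,
        band=band,
        degenerate=degenerate,
    )


def bland_altman(
    scores1: Sequence[float], scores2: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired totals (method 1 minus method 2).

    Differences are administered minus FFQ-derived throughout the package;
    limits of agreement are mean +/- 1.96 * SD of the differences.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ConfigurationError("scores must be paired equal-length vectors")
    if s1.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diff = s1 - s2
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    pairs = pd.DataFrame({"mean": (s1 + s2) / 2.0, "difference": diff})
    return BlandAltmanResult(
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pairs=pairs,
    )


def bland_altman_plot(result: BlandAltmanResult, path) -> None:
    """Write a Bland-Altman scatter with mean-difference and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.pairs["mean"], result.pairs["difference"], s=12, alpha=0.4)
    ax.axhline(result.mean_difference, color="k", lw=1.2)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("Mean of administered and FFQ-derived score")
    ax.set_ylabel("Administered − FFQ-derived score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def validate_items(
    questionnaire: pd.DataFrame,
    ffq_table: pd.DataFrame,
    registry=None,
    mapping=None,
    exclude_items: Sequence[int] = (11,),
    dichotomy_cutoff: int = scoring_mod.DEFAULT_DICHOTOMY_CUTOFF,
    policy: str = "complete_case",
) -> list[AgreementResult]:
    """Relative-validity analysis: per-item agreement plus the dichotomised
    total, between the administered screener and FFQ-derived indicators.

    Both tables are scored, paired on ``child_id``, and one
    :class:`AgreementResult` is produced per derivable item not in
    ``exclude_items``, plus one row ``"total"`` comparing the >=cutoff
    adherence classes.  Items with zero variance on both methods are
    flagged degenerate but retained.
    """
    if registry is None:
        registry = scoring_mod.load_registry()
    if mapping is None:
        mapping = ffq_mod.load_mapping()

    scored_q = scoring_mod.score_table(questionnaire, registry, policy=policy)
    scored_f = ffq_mod.derive_table(ffq_table, registry, mapping)
    merged = scored_q.merge(scored_f, on="child_id", suffixes=("_q", "_f"))
    if merged.empty:
        raise InsufficientDataError("no paired complete records to validate")

    items = [
        i for i in ffq_mod.derivable_items(mapping) if i not in set(exclude_items)
    ]
    labels = {c.item_id: c.label for c in registry}
    results = []
    for item_id in items:
        col = f"pt{item_id:02d}"
        table = build_2x2(merged[f"{col}_q"], merged[f"{col}_f"])
        results.append(agreement_from_table(str(item_id), labels[item_id], table))

    # total score dichotomised at the adherence cutoff, on each method's
    # own item set (18 administered items vs 17 derivable reference items)
    high_q = (merged["total_q"] >= dichotomy_cutoff).astype(int)
    high_f = (merged["total_f"] >= dichotomy_cutoff).astype(int)
    results.append(
        agreement_from_table(
            "total",
            f"Total score >= {dichotomy_cutoff} points",
            build_2x2(high_q, high_f),
        )
    )
    return results


def validation_report(results: Sequence[AgreementResult]) -> pd.DataFrame:
    """Serialise agreement results to a report table (percentages 0-100)."""
    rows = []
    for r in results:
        rows.append(
            {
                "item_id": r.key,
                "label": r.label,
                "n": r.n,
                "pct_med4child": 100.0 * r.prop_method1,
                "pct_ffq": 100.0 * r.prop_method2,
                "pct_agreement": 100.0 * r.percent_agreement,
                "kappa": r.kappa,
                "ci_low": r.kappa_ci[0],
                "ci_high": r.kappa_ci[1],
                "band": r.band if r.band is not None else "undefined",
            }
        )
    return pd.DataFrame(rows)
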
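"""Descriptive cohort statistics: mortality, categories, score distributions.

Proportions are reported as percentages with 95% confidence intervals.
The default interval is the Wald normal approximation with z = 1.96,
truncated to [0, 100] — the convention of the SPSS-era clinical literature
this package targets; the Wilson score interval is available by flag for
small samples and extreme proportions, via statsmodels.

Score distributions are summarized as median and interquartile range using
Tukey hinges (the quartile rule SPSS prints), isolated in
:func:`median_iqr` so an alternate rule is a one-line swap.

Raw values are kept unrounded internally; display rounding (1 decimal,
half-up) lives only in the formatting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .patient_model import ResolvedRecord
from .roc_analysis import split_by_outcome
from .severity_scores import (
    SCORE_NAMES,
    SCORERS,
    SepsisCategory,
    classify_sepsis,
)

__all__ = [
    "proportion_ci",
    "median_iqr",
    "survival_by_score",
    "CohortSummary",
    "summarize",
    "format_summary",
    "round_half_up",
]

_Z_WALD = 1.96


def proportion_ci(
    k: int, n: int, method: str = "wald"
) -> tuple[float, float, float]:
    """Binomial proportion with 95% CI, on the percent scale.

    ``method="wald"``: p +/- 1.96*sqrt(p(1-p)/n), truncated to [0, 100].
    ``method="wilson"``: Wilson score interval (never exits [0, 100] even
    before truncation).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    p = k / n
    if method == "wald":
        half = _Z_WALD * np.sqrt(p * (1.0 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    elif method == "wilson":
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return 100.0 * p, 100.0 * float(lo), 100.0 * float(hi)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (median, q1, q3) by Tukey hinges.

    The hinges are the medians of the lower and upper halves of the sorted
    data, each half including the overall median when n is odd.
    """
    if len(values) == 0:
        raise ValueError("median_iqr requires a non-empty list")
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    med = float(np.median(x))
    half = (n + 1) // 2  # include the median point in each half when n odd
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return med, q1, q3


def survival_by_score(
    records: Sequence[ResolvedRecord],
    score_name: str,
    bin_width: int = 1,
) -> pd.DataFrame:
    """Survival percentage stratified by score bin.

    Returns a DataFrame with columns ``bin`` (left edge of a
    ``bin_width``-wide score interval), ``n`` and ``survival_pct``; empty
    bins are omitted.  Unit-width bins (one row per observed total) by
    default.
    """
    if score_name not in SCORERS:
        raise KeyError(f"unknown score {score_name!r}")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    scorer = SCORERS[score_name]
    rows: dict[int, list[int]] = {}
    for r in records:
        if r.survived_to_discharge is None:
            raise ValueError(f"patient {r.id!r} has no recorded outcome")
        b = (scorer(r).total // bin_width) * bin_width
        rows.setdefault(b, []).append(int(r.survived_to_discharge))
    out = [
        {"bin": b, "n": len(v), "survival_pct": 100.0 * np.mean(v)}
        for b, v in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["bin", "n", "survival_pct"])


@dataclass(frozen=True)
class ScoreSummary:
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_survived: int
    n_died: int
    mortality_pct: float
    mortality_ci: tuple[float, float]
    category_counts: dict[SepsisCategory, int]
    category_pct: dict[SepsisCategory, tuple[float, float, float]]
    score_overall: dict[str, ScoreSummary]
    score_by_outcome: dict[str, dict[str, ScoreSummary]]  # "survivors"/"deaths"
    survival_by_score: dict[str, pd.DataFrame]


def summarize(
    records: Sequence[ResolvedRecord],
    infection_suspected: bool = True,
    score_names: Sequence[str] = SCORE_NAMES,
    bin_width: int = 1,
    ci_method: str = "wald",
) -> CohortSummary:
    """Assemble the full descriptive summary of an outcome-labelled cohort.

    Invariant to patient ordering.  Categories come from
    :func:`sepscore.severity_scores.classify_sepsis` applied per patient.
    """
    n = len(records)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    outcomes = []
    for r in records:
        if r.survived_to_discharge is None:
            raise ValueError(f"patient {r.id!r} has no recorded outcome")
        outcomes.append(r.survived_to_discharge)
    n_survived = sum(outcomes)
    n_died = n - n_survived

    mort, mlo, mhi = proportion_ci(n_died, n, method=ci_method)

    cat_counts = {c: 0 for c in SepsisCategory}
    for r in records:
        cat_counts[classify_sepsis(r, infection_suspected).category] += 1
    cat_pct = {
        c: proportion_ci(k, n, method=ci_method) for c, k in cat_counts.items()
    }

    overall: dict[str, ScoreSummary] = {}
    by_outcome: dict[str, dict[str, ScoreSummary]] = {}
    strat: dict[str, pd.DataFrame] = {}
    for name in score_names:
        pos, neg = split_by_outcome(records, name)
        overall[name] = ScoreSummary(*median_iqr(pos + neg))
        by_outcome[name] = {
            "survivors": ScoreSummary(*median_iqr(neg)) if neg else None,
            "deaths": ScoreSummary(*median_iqr(pos)) if pos else None,
        }
        strat[name] = survival_by_score(records, name, bin_width=bin_width)

    return CohortSummary(
        n=n,
        n_survived=n_survived,
        n_died=n_died,
        mortality_pct=mort,
        mortality_ci=(mlo, mhi),
        category_counts=cat_counts,
        category_pct=cat_pct,
        score_overall=overall,
        score_by_outcome=by_outcome,
        survival_by_score=strat,
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_summary(s: CohortSummary) -> str:
    """Human-readable report; all percents rounded to 1 decimal, half-up."""
    r1 = round_half_up
    lines = [
        f"Cohort: n={s.n} ({s.n_survived} survivors, {s.n_died} deaths)",
        f"In-hospital mortality: {r1(s.mortality_pct)}% "
        f"(95% CI {r1(s.mortality_ci[0])}-{r1(s.mortality_ci[1])})",
        "Sepsis categories:",
    ]
    for c, k in s.category_counts.items():
        pct, lo, hi = s.category_pct[c]
        lines.append(
            f"  {c.value}: {k} ({r1(pct)}%; 95% CI {r1(lo)}-{r1(hi)})"
        )
    lines.append("Score distributions (median [IQR]):")
    for name, ov in s.score_overall.items():
        parts = [f"overall {ov.median:g} [{ov.q1:g}-{ov.q3:g}]"]
        for label in ("survivors", "deaths"):
            ss = s.score_by_outcome[name][label]
            if ss is not None:
                parts.append(f"{label} {ss.median:g} [{ss.q1:g}-{ss.q3:g}]")
        lines.append(f"  {name}: " + "; ".join(parts))
    return "\n".join(lines)
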
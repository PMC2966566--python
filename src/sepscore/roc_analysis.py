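"""ROC-curve construction and AUC estimation for integer-valued scores.

Deaths are the positive class everywhere in this package, and a higher
score is read as more death-like; this orientation is fixed centrally in
:func:`split_by_outcome` so it cannot silently invert.

The AUC is the Mann–Whitney probability that a randomly chosen non-survivor
outscores a randomly chosen survivor, with ties credited one half:

    AUC = (#{pos > neg} + 0.5 * #{pos = neg}) / (n_pos * n_neg)

Severity scores are small integers, so ties dominate; the half-tie
convention is exactly what makes the pair-count AUC coincide with the
trapezoidal area under the empirical ROC curve, and :func:`roc_points`
is constructed so the two agree to floating-point precision.

Confidence intervals come in two flavours, reported side by side by
default: the DeLong structural-components variance with a normal
approximation (the standard nonparametric CI for a single AUC), and a
stratified percentile bootstrap that resamples within outcome groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .patient_model import ResolvedRecord
from .severity_scores import SCORERS

__all__ = [
    "RocResult",
    "auc_mann_whitney",
    "roc_points",
    "delong_variance",
    "auc_ci",
    "split_by_outcome",
    "compare_scores",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RocResult:
    """AUC with its 95% CI and operating points for one score vs mortality."""

    score_name: str
    auc: float
    ci_low: float
    ci_high: float
    method: str  # "delong" or "bootstrap"
    operating_points: tuple[tuple[float, float, float], ...]  # (thr, sens, spec)
    n_pos: int  # deaths
    n_neg: int  # survivors

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0


def _check_nonempty(pos: Sequence[float], neg: Sequence[float]) -> None:
    if len(pos) == 0:
        raise ValueError("positive class (deaths) is empty")
    if len(neg) == 0:
        raise ValueError("negative class (survivors) is empty")


def auc_mann_whitney(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> float:
    """Tie-corrected Mann–Whitney AUC; deaths positive, higher score worse.

    Computed via midranks (O(n log n)), equivalent to exhaustive pair
    counting with half credit for ties.
    """
    _check_nonempty(pos_scores, neg_scores)
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[tuple[float, float, float], ...]:
    """Operating points (threshold, sensitivity, specificity).

    One point per distinct observed score value (predict death when
    score >= threshold) plus a +inf sentinel giving (sens, spec) = (0, 1).
    The trapezoidal area over these points in (1 - spec, sens) space equals
    :func:`auc_mann_whitney`.
    """
    _check_nonempty(pos_scores, neg_scores)
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(math.inf, 0.0, 1.0)]
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        pts.append((float(t), sens, spec))
    return tuple(pts)


def trapezoidal_auc(
    points: Sequence[tuple[float, float, float]]
) -> float:
    """Area under the (1 - spec, sens) polyline of :func:`roc_points`."""
    fpr = np.array([1.0 - spec for _, _, spec in points])
    tpr = np.array([sens for _, sens, _ in points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def delong_variance(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> float:
    """DeLong variance of the AUC from structural components.

    For each death i the placement value V10_i is the fraction of survivors
    it outscores (half credit for ties), and symmetrically V01_j for each
    survivor; var(AUC) = S10/m + S01/n with sample variances S and class
    sizes m, n.  Requires at least two observations per class.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            "DeLong variance requires >= 2 observations in each outcome class"
        )
    # placement values via broadcast comparison
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    mat = gt + 0.5 * eq
    v10 = mat.mean(axis=1)
    v01 = 1.0 - mat.mean(axis=0)  # fraction of deaths a survivor "beats"
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    return s10 / len(pos) + s01 / len(neg)


def auc_ci(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    method: str = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    score_name: str = "",
) -> RocResult:
    """AUC with a 95% confidence interval.

    ``method="delong"``: normal-approximation CI from the DeLong variance,
    truncated to [0, 1].  ``method="bootstrap"``: stratified percentile
    bootstrap resampling within each outcome group (``n_boot`` >= 1000
    recommended; ``seed`` required for reproducibility).
    """
    _check_nonempty(pos_scores, neg_scores)
    auc = auc_mann_whitney(pos_scores, neg_scores)
    if method == "delong":
        se = math.sqrt(delong_variance(pos_scores, neg_scores))
        lo = max(0.0, auc - _Z975 * se)
        hi = min(1.0, auc + _Z975 * se)
    elif method == "bootstrap":
        if n_boot < 1000:
            raise ValueError(f"bootstrap needs n_boot >= 1000, got {n_boot}")
        if seed is None:
            raise ValueError("bootstrap CI requires an explicit seed")
        rng = np.random.default_rng(seed)
        pos = np.asarray(pos_scores, dtype=float)
        neg = np.asarray(neg_scores, dtype=float)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=len(pos), replace=True)
            n = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = auc_mann_whitney(p, n)
        lo, hi = (float(q) for q in np.quantile(reps, [0.025, 0.975]))
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RocResult(
        score_name=score_name,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        method=method,
        operating_points=roc_points(pos_scores, neg_scores),
        n_pos=len(pos_scores),
        n_neg=len(neg_scores),
    )


def split_by_outcome(
    records: Sequence[ResolvedRecord], score_name: str
) -> tuple[list[int], list[int]]:
    """Score a cohort and split totals into (deaths, survivors).

    This is the single place where the class orientation is fixed:
    non-survivors are the positive class.
    """
    if score_name not in SCORERS:
        raise KeyError(
            f"unknown score {score_name!r}; available: {', '.join(SCORERS)}"
        )
    scorer = SCORERS[score_name]
    pos: list[int] = []
    neg: list[int] = []
    for r in records:
        if r.survived_to_discharge is None:
            raise ValueError(
                f"patient {r.id!r} has no recorded outcome; "
                "evaluation requires survived_to_discharge"
            )
        (neg if r.survived_to_discharge else pos).append(scorer(r).total)
    return pos, neg


def compare_scores(
    records: Sequence[ResolvedRecord],
    score_names: Sequence[str] = ("MEDS", "mREMS", "CURB65"),
    method: str = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> list[RocResult]:
    """Discrimination of several scores on the identical patient set.

    Returns one :class:`RocResult` per score, ranked by AUC (best first).
    """
    results = [
        auc_ci(*split_by_outcome(records, name), method=method,
               n_boot=n_boot, seed=seed, score_name=name)
        for name in score_names
    ]
    return sorted(results, key=lambda r: r.auc, reverse=True)
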
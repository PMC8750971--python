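"""Diagnostic and group statistics for scored cohorts.

ROC/Youden analysis of cases versus controls, cut-off
sensitivity/specificity tables, Wilcoxon rank-sum group comparisons with
Benjamini-Hochberg adjustment, Pearson correlation, Welch t-tests, and
the one-sample noncentral-t power calculation used for study sizing.

Conventions: a sample is called positive when its score strictly exceeds
the threshold; specificity is the fraction of controls at or below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LABELS = (
    "control",
    "upfront",
    "CTX",
    "follow-up",
    "platinum-eligible",
    "platinum-non-eligible",
)


@dataclass
class RocResult:
    """ROC curve of case scores against control scores.

    ``thresholds`` are midpoints between consecutive distinct pooled scores
    plus -inf/+inf sentinels; positive means score > threshold.  The Youden
    threshold maximizes sensitivity + specificity - 1, ties broken toward
    the lowest threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc(controls: Sequence[float], cases: Sequence[float]) -> RocResult:
    """ROC analysis with trapezoid AUC (equals the Mann-Whitney statistic)."""
    ctrl = np.asarray(controls, dtype=float)
    case = np.asarray(cases, dtype=float)
    if ctrl.size == 0 or case.size == 0:
        raise ValueError("both controls and cases must be non-empty")
    pooled = np.unique(np.concatenate([ctrl, case]))
    mids = (pooled[:-1] + pooled[1:]) / 2 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(case > t).mean() for t in thresholds])
    spec = np.array([(ctrl <= t).mean() for t in thresholds])
    # trapezoid over the (1 - spec, sens) curve; thresholds ascend so FPR descends
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax takes the first (lowest) threshold on ties
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thresholds[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
    )


def cutoff_table(
    controls: Sequence[float],
    case_groups: Mapping[str, Sequence[float]],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Specificity and per-group/pooled sensitivity at each cut-off.

    Specificity = fraction of controls <= cutoff; sensitivity = fraction of
    cases > cutoff.  Values are exact fractions; use :func:`format_percent`
    only at presentation time.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be non-empty")
    ctrl = np.asarray(controls, dtype=float)
    groups = {k: np.asarray(v, dtype=float) for k, v in case_groups.items()}
    pooled = (
        np.concatenate(list(groups.values())) if groups else np.empty(0)
    )
    rows = []
    for c in cutoffs:
        row = {"cutoff": c, "specificity": float((ctrl <= c).mean()) if ctrl.size else np.nan}
        for label, scores in groups.items():
            row[f"sensitivity_{label}"] = float((scores > c).mean())
        row["sensitivity_pooled"] = float((pooled > c).mean()) if pooled.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cutoff")


def format_percent(fraction: float) -> int:
    """Nearest-integer percent, half away from zero (97.5% -> 98%)."""
    import math

    x = fraction * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 8 observations and no ties;
    otherwise the normal approximation with continuity and tie correction.
    Returns (U statistic for group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate constant groups: t undefined by the formula; report
        # no evidence of difference when means agree, certainty otherwise
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pairwise_comparisons(
    scores_by_group: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """All pairwise Wilcoxon rank-sum tests with BH adjustment."""
    pairs = list(combinations(scores_by_group, 2))
    if not pairs:
        raise ValueError("need at least two groups")
    rows = []
    for ga, gb in pairs:
        u, p = wilcoxon_rank_sum(scores_by_group[ga], scores_by_group[gb])
        rows.append({"group_a": ga, "group_b": gb, "statistic": u, "p": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    return table


def one_sample_t_power(n: int, effect_size: float, alpha: float) -> float:
    """Exact power of the one-sided one-sample t-test at size n."""
    if n < 2:
        return 0.0
    t_crit = stats.t.ppf(1.0 - alpha, n - 1)
    return float(stats.nct.sf(t_crit, n - 1, effect_size * np.sqrt(n)))


def one_sample_t_sample_size(
    mean_difference: float = 2.0,
    sigma: float = 4.0,
    alpha: float = 0.01,
    power: float = 0.95,
    max_n: int = 100_000,
) -> int:
    """Smallest n whose exact noncentral-t power reaches the target.

    One-sample, one-sided design at level ``alpha`` with effect size
    d = mean_difference / sigma and noncentrality d * sqrt(n).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sigma <= 0 or mean_difference <= 0:
        raise ValueError("mean_difference and sigma must be positive")
    if power <= alpha or power >= 1:
        raise ValueError("power must lie in (alpha, 1)")
    d = mean_difference / sigma
    for n in range(2, max_n + 1):
        if one_sample_t_power(n, d, alpha) >= power:
            return n
    raise ValueError(f"no n <= {max_n} reaches power {power}")
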
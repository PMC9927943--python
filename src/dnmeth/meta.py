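"""Cross-cohort meta-analysis of core-gene methylation differences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "median_difference",
    "weighted_meta_median",
    "fisher_combined",
]

P_FLOOR = 1e-300


@dataclass
class MetaResult:
    per_cohort: list  # (name, estimate, n, p)
    pooled: float
    weights: np.ndarray
    fisher_x2: float
    combined_p: float


def median_difference(group_a, group_b, n_boot: int = 2000, seed: int = 0):
    """median(b) - median(a) with a 95% percentile bootstrap CI.

    Returns ``(difference, (ci_low, ci_high))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    diff = float(np.median(b) - np.median(a))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(b, len(b))) - np.median(rng.choice(a, len(a)))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi))


def weighted_meta_median(estimates, sizes) -> float:
    """Sample-size-weighted mean of cohort estimates."""
    est = np.asarray(estimates, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if len(est) == 0:
        raise ValueError("need at least one cohort")
    if len(est) != len(n):
        raise ValueError("estimates and sizes must match")
    if (n < 0).any() or n.sum() == 0:
        raise ValueError("cohort sizes must be non-negative with positive total")
    w = n / n.sum()
    return float((w * est).sum())


def fisher_combined(pvalues):
    """Fisher's combined probability test.

    ``X2 = -2 * sum(ln p_i)``; combined p is the upper tail of chi-square
    with 2k degrees of freedom. Raises on p = 0 (callers must floor their
    p-values, e.g. at 1e-300).
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros before calling")
    x2 = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(x2, 2 * len(p)))
    return x2, max(min(combined, 1.0), 0.0)


def meta_analyze(cohort_data: dict, mannwhitney_p: dict | None = None, seed: int = 0) -> MetaResult:
    """Pool per-cohort median methylation differences and combine evidence.

    ``cohort_data`` maps cohort name -> (low_risk_values, risk_values);
    ``mannwhitney_p`` optionally supplies per-cohort p-values (otherwise the
    normal-approximation Mann-Whitney p is computed here).
    """
    from .cohort import group_compare_mannwhitney

    per_cohort = []
    estimates, sizes, pvals = [], [], []
    for name, (low, risk) in cohort_data.items():
        diff, _ = median_difference(low, risk, seed=seed)
        n = len(low) + len(risk)
        if mannwhitney_p is not None and name in mannwhitney_p:
            p = mannwhitney_p[name]
        else:
            values = np.concatenate([low, risk])
            groups = np.array(["low"] * len(low) + ["risk"] * len(risk))
            p = float(group_compare_mannwhitney(values, groups, "low")["p"].iloc[0])
        p = max(p, P_FLOOR)
        per_cohort.append((name, diff, n, p))
        estimates.append(diff)
        sizes.append(n)
        pvals.append(p)
    pooled = weighted_meta_median(estimates, sizes)
    x2, combined = fisher_combined(pvals)
    w = np.asarray(sizes, dtype=float)
    return MetaResult(
        per_cohort=per_cohort, pooled=pooled, weights=w / w.sum(),
        fisher_x2=x2, combined_p=combined,
    )
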
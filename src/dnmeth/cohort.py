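"""Core-gene methylation index and cross-sectional cohort statistics.

Builds the combined methylation index from per-subject methyl-qPCR
percentages of the seven core genes via PC1-loading weights, rescaled so a
reference group's mean is 100%, and provides the Mann-Whitney group
contrasts and Pearson covariate correlations used to characterize it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CORE_GENES",
    "MethylationIndex",
    "combine_core_genes",
    "mannwhitney_u",
    "group_compare_mannwhitney",
    "correlate_covariate",
    "hba1c_percent_to_mmol",
    "hba1c_mmol_to_percent",
]

CORE_GENES = ("MTOR", "RPTOR", "IRS2", "TXNRD1", "LCAT", "SMPD3", "COL1A2")

# exact-enumeration cutoff for the Mann-Whitney test
_EXACT_N = 20


@dataclass
class MethylationIndex:
    values: pd.Series  # per-subject combined %, reference-group mean = 100
    weights: np.ndarray  # PC1 loadings, unit norm, non-negative sum
    genes: tuple
    reference_group: object
    scale: float  # multiplicative factor applied to the raw loading-weighted sum


def combine_core_genes(
    table: pd.DataFrame,
    genes=CORE_GENES,
    group_col: str = "group",
    reference_group="low",
) -> MethylationIndex:
    """Combine per-gene methylation percentages into one index per subject.

    PC1 loadings of the column-centered subject x gene matrix (sign fixed so
    the loading sum is >= 0) weight the raw gene percentages; the raw index is
    then rescaled so the reference group's mean is exactly 100%. Subjects with
    any missing core gene are dropped (complete case).
    """
    genes = [g for g in genes if g in table.columns]
    if not genes:
        raise ValueError("no core gene columns present")
    sub = table.dropna(subset=genes)
    if len(sub) < 2:
        raise ValueError("need at least 2 complete-case subjects")
    ref_mask = sub[group_col] == reference_group
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    X = sub[genes].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        warnings.warn("constant methylation matrix: PC1 undefined, using equal weights")
        w = np.full(len(genes), 1.0 / np.sqrt(len(genes)))
    else:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        w = Vt[0]
        if w.sum() < 0:
            w = -w
    raw = X @ w
    ref_mean = raw[ref_mask.to_numpy()].mean()
    if ref_mean <= 0:
        raise ValueError("reference-group raw index mean is non-positive; cannot rescale")
    scale = 100.0 / ref_mean
    values = pd.Series(raw * scale, index=sub.index, name="methylation_index")
    return MethylationIndex(
        values=values, weights=w, genes=tuple(genes),
        reference_group=reference_group, scale=scale,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def mannwhitney_u(x, y) -> float:
    """U statistic for group x vs y with midrank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2


def _mannwhitney_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all group assignments."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    mu = n1 * (n - n1) / 2
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    ranks = _midranks(pooled)
    for combo in itertools.combinations(range(n), n1):
        r1 = ranks[list(combo)].sum()
        u = r1 - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def _mannwhitney_normal_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (u_obs - mu) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def group_compare_mannwhitney(
    values, groups, reference, compare_to=None
) -> pd.DataFrame:
    """Mann-Whitney U of each group against the reference group.

    Exact enumeration when the combined sample is small (n1+n2 <= 20),
    normal approximation with tie correction otherwise. Returns one row per
    compared group with U, p, method, and group sizes.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ref = values[groups == reference]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    labels = compare_to if compare_to is not None else [
        g for g in dict.fromkeys(groups) if g != reference
    ]
    rows = []
    for g in labels:
        other = values[groups == g]
        if len(other) == 0:
            raise ValueError(f"group {g!r} is empty")
        u = mannwhitney_u(other, ref)
        if len(other) + len(ref) <= _EXACT_N:
            p = _mannwhitney_exact_p(other, ref, u)
            method = "exact"
        else:
            p = _mannwhitney_normal_p(other, ref, u)
            method = "normal"
        rows.append({"group": g, "n": len(other), "n_ref": len(ref), "U": u, "p": p, "method": method})
    return pd.DataFrame(rows)


def correlate_covariate(index_values, covariate_values):
    """Pearson r, two-sided p, and least-squares line for index vs covariate.

    p is from ``t = r * sqrt((n-2)/(1-r^2))`` against Student t with n-2 df.
    Returns ``(r, p, slope, intercept)``.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched series of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in input series")
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
    n = len(x)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    slope = float((xm * ym).sum() / (xm**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    return r, p, slope, intercept


def hba1c_percent_to_mmol(pct):
    """NGSP % -> IFCC mmol/mol."""
    return 10.93 * np.asarray(pct, dtype=float) - 23.50


def hba1c_mmol_to_percent(mmol):
    """IFCC mmol/mol -> NGSP %."""
    return (np.asarray(mmol, dtype=float) + 23.50) / 10.93
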
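"""Region-level differential methylation.

Normalizes methyl-capture region counts, estimates a common negative-binomial
dispersion, runs a two-group NB exact test conditional on the pooled total,
calls differentially methylated regions (DMRs) across all pairwise group
contrasts, clusters DMR profiles, and projects samples with PCA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "RegionCountMatrix",
    "DmrRecord",
    "normalize_log_cpm",
    "estimate_dispersion",
    "nb_exact_test",
    "adjust_covariates",
    "call_dmrs",
    "cluster_dmr_profiles",
    "sample_pca",
    "bh_qvalues",
]

# relative tolerance used to stabilize floating-point ties when enumerating
# outcomes no more probable than the observed split
_TIE_RTOL = 1e-12


@dataclass
class RegionCountMatrix:
    """Genomic regions x samples integer counts with design metadata.

    Attributes
    ----------
    regions : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end`` (0-based half-open).
    counts : numpy.ndarray
        Integer matrix, shape (n_regions, n_samples), all values >= 0.
    design : pandas.DataFrame
        One row per sample; must contain a ``group`` column, any other
        columns are treated as adjustment covariates.
    library_sizes : numpy.ndarray
        Per-sample library totals (> 0). Defaults to column sums of counts.
    """

    regions: pd.DataFrame
    counts: np.ndarray
    design: pd.DataFrame
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.design) != self.counts.shape[1]:
            raise ValueError("design rows must match count columns")
        if "group" not in self.design.columns:
            raise ValueError("design must contain a 'group' column")
        if len(self.regions) != self.counts.shape[0]:
            raise ValueError("regions must match count rows")
        if (self.regions["start"] >= self.regions["end"]).any():
            raise ValueError("regions must satisfy start < end")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance in the design."""
        return list(dict.fromkeys(self.design["group"]))

    def group_columns(self, label) -> np.ndarray:
        return np.flatnonzero((self.design["group"] == label).to_numpy())


@dataclass
class DmrRecord:
    """One tested region with per-contrast p-values and its DMR call."""

    chrom: str
    start: int
    end: int
    pvalues: dict  # (group_a, group_b) -> p
    log2_fold: dict  # case label -> log2 fold difference vs control
    direction: str | None  # 'hypo' or 'hyper' in cases, None if not called
    cluster: int | None  # 1..k significance-pattern cluster, None if not called
    significant: bool
    qvalues: dict = field(default_factory=dict)


def normalize_log_cpm(matrix: RegionCountMatrix, pseudocount: float = 0.5) -> np.ndarray:
    """log2 counts-per-million: ``log2(count / library_size * 1e6 + pseudocount)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lib = matrix.library_sizes
    cpm = matrix.counts / lib[np.newaxis, :] * 1e6
    return np.log2(cpm + pseudocount)


def estimate_dispersion(matrix: RegionCountMatrix) -> float:
    """Common NB dispersion phi (Var = mu + phi * mu^2) by pooled method of moments.

    Within-group sample means and variances are pooled across all regions and
    groups via the ratio estimator ``sum(var - mean) / sum(mean^2)``, clipped
    at zero.
    """
    num = 0.0
    den = 0.0
    for label in matrix.groups:
        cols = matrix.group_columns(label)
        if len(cols) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        sub = matrix.counts[:, cols].astype(float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m * m))
    if den == 0.0:
        return 0.0
    return max(0.0, num / den)


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    # scipy parameterization: n = size, p = size / (size + mean)
    p = size / (size + mean)
    return stats.nbinom.logpmf(k, size, p)


def nb_exact_test(counts_a, counts_b, dispersion: float) -> float:
    """Two-sided NB exact test for a two-group comparison.

    Conditional on the pooled total ``S``, the group-A sum is compared against
    its null distribution: the sum of ``n_a`` i.i.d. NB(mu, phi) variables is
    NB with mean ``n_a * mu`` and size ``n_a / phi``. The p-value sums the
    probabilities of every split of ``S`` whose joint probability does not
    exceed the observed one, normalized by the total over all splits. With
    ``phi = 0`` this reduces to the Poisson-conditional binomial exact test.

    Counts must be on equalized library sizes (normalize or pass size-factor
    adjusted counts).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    sum_a = int(round(a.sum()))
    sum_b = int(round(b.sum()))
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    x = np.arange(total + 1)
    if dispersion == 0:
        # Poisson group sums -> conditional distribution is binomial
        log_pa = stats.poisson.logpmf(x, n_a * mu)
        log_pb = stats.poisson.logpmf(total - x, n_b * mu)
    else:
        log_pa = _nb_logpmf(x, n_a * mu, n_a / dispersion)
        log_pb = _nb_logpmf(total - x, n_b * mu, n_b / dispersion)
    log_joint = log_pa + log_pb
    log_obs = log_joint[sum_a]
    keep = log_joint <= log_obs + np.log1p(_TIE_RTOL)
    # normalize within the conditional support
    m = log_joint.max()
    probs = np.exp(log_joint - m)
    p = float(probs[keep].sum() / probs.sum())
    return min(1.0, p)


def adjust_covariates(log_cpm: np.ndarray, design: pd.DataFrame) -> np.ndarray:
    """Per-region least-squares residuals of log-CPM on covariates.

    Group labels are excluded from the regression so group-mean structure is
    preserved. Covariates are taken as every design column except ``group``;
    non-numeric columns are factor-coded. Raises on rank deficiency.
    """
    covars = design.drop(columns=["group"], errors="ignore")
    n = len(design)
    blocks = [np.ones((n, 1))]
    for col in covars.columns:
        series = covars[col]
        if pd.api.types.is_numeric_dtype(series):
            blocks.append(series.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(series, drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    # constant covariates collapse onto the intercept; only genuine
    # collinearity between non-constant columns is an error
    varying = X[:, [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]]
    if np.linalg.matrix_rank(varying) < varying.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear covariates)")
    X = varying
    coef, *_ = np.linalg.lstsq(X, log_cpm.T, rcond=None)
    fitted = X @ coef
    return log_cpm - fitted.T


def _equalize_counts(matrix: RegionCountMatrix) -> np.ndarray:
    """Scale counts to the mean library size and round to integers."""
    target = matrix.library_sizes.mean()
    factors = target / matrix.library_sizes
    return np.rint(matrix.counts * factors[np.newaxis, :]).astype(np.int64)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_dmrs(
    matrix: RegionCountMatrix,
    alpha: float = 0.01,
    dispersion: float | None = None,
    control_group=None,
) -> list[DmrRecord]:
    """Call DMRs across all pairwise group contrasts at threshold ``alpha``.

    Every pairwise contrast (4 groups -> 6 contrasts) is tested with
    :func:`nb_exact_test` on library-size-equalized counts. A region is a DMR
    if any case-vs-control p-value falls below ``alpha``; direction comes from
    the sign of the log2 fold difference. Cluster labels follow the
    significance pattern across case groups: if every case group is
    significantly hyper-methylated the region joins the hyper-in-all-cases
    cluster (label = n_cases + 1); otherwise the label is the index (1-based,
    highest-risk case group first) of the most advanced case group with a
    significant hypo call.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    groups = matrix.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    control = groups[0] if control_group is None else control_group
    cases = [g for g in groups if g != control]

    counts = _equalize_counts(matrix)
    if dispersion is None:
        dispersion = estimate_dispersion(matrix)

    cols = {g: matrix.group_columns(g) for g in groups}
    pair_list = list(itertools.combinations(groups, 2))
    n_regions = matrix.n_regions

    pvals = {pair: np.ones(n_regions) for pair in pair_list}
    for pair in pair_list:
        ca, cb = cols[pair[0]], cols[pair[1]]
        for i in range(n_regions):
            pvals[pair][i] = nb_exact_test(counts[i, ca], counts[i, cb], dispersion)
    qvals = {pair: bh_qvalues(pvals[pair]) for pair in pair_list}

    # log2 fold of each case group vs control on mean equalized counts
    eps = 0.5
    ctrl_mean = counts[:, cols[control]].mean(axis=1)
    log2_fold = {
        g: np.log2((counts[:, cols[g]].mean(axis=1) + eps) / (ctrl_mean + eps))
        for g in cases
    }

    def contrast_p(g, i):
        pair = (control, g) if (control, g) in pvals else (g, control)
        return pvals[pair][i]

    records: list[DmrRecord] = []
    n_cases = len(cases)
    for i in range(n_regions):
        sig_hypo = [g for g in cases if contrast_p(g, i) < alpha and log2_fold[g][i] < 0]
        sig_hyper = [g for g in cases if contrast_p(g, i) < alpha and log2_fold[g][i] > 0]
        significant = bool(sig_hypo or sig_hyper)
        direction = None
        cluster = None
        if significant:
            if len(sig_hyper) == n_cases:
                direction = "hyper"
                cluster = n_cases + 1
            elif sig_hypo:
                direction = "hypo"
                # most advanced (latest-listed) case group with a hypo call;
                # label 1 = highest-risk group, matching cluster ordering
                idx = max(cases.index(g) for g in sig_hypo)
                cluster = n_cases - idx
            else:
                direction = "hyper"
                cluster = n_cases + 1
        row = matrix.regions.iloc[i]
        records.append(
            DmrRecord(
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                pvalues={pair: float(pvals[pair][i]) for pair in pair_list},
                log2_fold={g: float(log2_fold[g][i]) for g in cases},
                direction=direction,
                cluster=cluster,
                significant=significant,
                qvalues={pair: float(qvals[pair][i]) for pair in pair_list},
            )
        )
    return records


def correlation_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; zero-variance rows get distance 1."""
    profiles = np.asarray(profiles, dtype=float)
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance profile: correlation undefined, distance set to 1")
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    safe = np.where(norm == 0, 1.0, norm)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    n = len(profiles)
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def cluster_dmr_profiles(profiles: np.ndarray, k: int):
    """Agglomerative clustering of DMR profiles.

    Distance is 1 - Pearson correlation between row profiles, linkage is
    average. Returns ``(labels, linkage_matrix)`` with labels in 1..k.
    """
    profiles = np.asarray(profiles, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) < k:
        raise ValueError("need at least k profiles")
    condensed = correlation_distance_matrix(profiles)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def sample_pca(adjusted_log_cpm: np.ndarray, n_components: int = 2):
    """PCA of samples from an adjusted log-CPM matrix (regions x samples).

    Samples are treated as observations; each region (feature) is centered.
    Returns ``(scores, loadings, explained_variance)`` where scores are the
    sample coordinates (U * S) and component signs are fixed so each
    component's loading sum is >= 0.
    """
    X = np.asarray(adjusted_log_cpm, dtype=float).T  # samples x regions
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("matrix has no variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(S))
    signs = np.where(Vt.sum(axis=1) >= 0, 1.0, -1.0)
    U = U * signs[np.newaxis, :]
    Vt = Vt * signs[:, np.newaxis]
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    explained = S[:n_components] ** 2 / (X.shape[0] - 1)
    return scores, loadings, explained
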
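"""Longitudinal outcomes and prediction of eGFR decline.

Classifies eGFR slope into no/slow/steep decline bands, flags albuminuria
progression, fits logistic risk models by IRLS, computes ROC AUC via the
rank statistic, and measures the added value of the methylation index with a
bootstrap delta-AUC test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import _midranks

__all__ = [
    "ProgressionOutcome",
    "PredictionModel",
    "egfr_slope",
    "classify_decline",
    "classify_albuminuria_progression",
    "fit_logistic",
    "roc_auc",
    "bootstrap_delta_auc",
]

DECLINE_CLASSES = ("none", "slow", "steep")
ALBUMINURIA_ORDER = {"Normo": 0, "Micro": 1, "Macro": 2, "ESRD": 3}


@dataclass
class ProgressionOutcome:
    egfr_slope: float
    decline_class: str
    albuminuria_progressor: bool | None
    followup_span: float


@dataclass
class PredictionModel:
    feature_names: list
    coefficients: np.ndarray  # intercept first, on standardized features
    feature_means: np.ndarray
    feature_sds: np.ndarray
    scores: np.ndarray  # fitted probabilities
    auc: float
    n_iter: int = 0
    delta_auc: float | None = None
    bootstrap_p: float | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        eta = self.coefficients[0] + Z @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def egfr_slope(followup) -> float:
    """(last eGFR - first eGFR) / (last time - first time); only the
    endpoints of the series are used."""
    pts = list(followup)
    if len(pts) < 2:
        raise ValueError("need at least 2 time points")
    times = [t for t, _ in pts]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("follow-up times must be strictly increasing")
    (t0, e0), (t1, e1) = pts[0], pts[-1]
    return (e1 - e0) / (t1 - t0)


def classify_decline(slope: float) -> str:
    """No decline if slope >= -1; slow if -3 < slope < -1; steep if <= -3.

    The boundary at exactly -3 is assigned to steep (conservative toward
    higher risk).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope >= -1:
        return "none"
    if slope > -3:
        return "slow"
    return "steep"


def classify_albuminuria_progression(baseline_stage: str, last_stage: str) -> bool:
    """Progressor iff the last albuminuria stage strictly exceeds baseline.

    Regression (improvement) counts as nonprogressor.
    """
    for stage in (baseline_stage, last_stage):
        if stage not in ALBUMINURIA_ORDER:
            raise ValueError(f"unknown albuminuria stage {stage!r}")
    return ALBUMINURIA_ORDER[last_stage] > ALBUMINURIA_ORDER[baseline_stage]


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    return (X - means) / sds, means, sds


def fit_logistic(
    X, y, feature_names=None, max_iter: int = 100, tol: float = 1e-8
) -> PredictionModel:
    """Maximum-likelihood logistic regression by IRLS on standardized features.

    Converges when the max absolute coefficient change drops below ``tol``.
    Divergence of the coefficient norm (perfect separation) aborts with a
    diagnostic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    Z, means, sds = _standardize(X)
    n, p = Z.shape
    # constant features carry no information; fit without them and report 0
    varying = np.flatnonzero(X.std(axis=0) > 0)
    A = np.hstack([np.ones((n, 1)), Z[:, varying]])
    beta_a = np.zeros(len(varying) + 1)
    beta_a[0] = np.log(y.mean() / (1 - y.mean()))
    n_iter = 0
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        eta = A @ beta_a
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z_work = eta + (y - mu) / w
        WA = A * w[:, None]
        beta_new = np.linalg.solve(A.T @ WA, A.T @ (w * z_work))
        if np.linalg.norm(beta_new) > 1e4:
            raise FloatingPointError("perfect separation detected: coefficients diverge")
        delta = np.abs(beta_new - beta_a).max()
        beta_a = beta_new
        if delta < tol:
            break
    if delta >= tol and np.abs(A @ beta_a).max() > 20:
        # non-convergence with saturated fitted probabilities: separation
        raise FloatingPointError("perfect separation detected: coefficients diverge")
    beta = np.zeros(p + 1)
    beta[0] = beta_a[0]
    beta[1 + varying] = beta_a[1:]
    scores = 1.0 / (1.0 + np.exp(-(beta[0] + Z @ beta[1:])))
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    return PredictionModel(
        feature_names=names, coefficients=beta, feature_means=means,
        feature_sds=sds, scores=scores, auc=roc_auc(scores, y), n_iter=n_iter,
    )


def roc_auc(scores, labels) -> float:
    """AUC as the midrank U statistic / (n1*n0); ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = _midranks(s)
    r_pos = ranks[pos].sum()
    u = r_pos - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def bootstrap_delta_auc(
    X_full,
    nested_columns,
    y,
    B: int = 500,
    seed: int = 0,
    max_retries: int = 100,
):
    """Added predictive value of the full model over the nested model.

    Both models are fit on the observed data to give the point estimate
    ``delta_auc = AUC(full) - AUC(nested)``, then refit on ``B`` bootstrap
    resamples of subjects. The two-sided p is the proportion of resampled
    deltas <= 0, doubled and clipped to [2/B, 1]. Resamples with a single
    outcome class are redrawn (bounded retries).

    Returns ``(delta_auc, p, full_model, nested_model, boot_deltas)``.
    """
    X_full = np.asarray(X_full, dtype=float)
    y = np.asarray(y, dtype=float)
    nested_columns = list(nested_columns)
    if B < 200:
        raise ValueError("B must be >= 200")
    if not set(nested_columns) <= set(range(X_full.shape[1])):
        raise ValueError("nested columns must index full-model features")
    full = fit_logistic(X_full, y)
    nested = fit_logistic(X_full[:, nested_columns], y)
    delta = full.auc - nested.auc

    rng = np.random.default_rng(seed)
    n = len(y)
    deltas = np.empty(B)
    for b in range(B):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a bootstrap resample with both classes")
        Xb = X_full[idx]
        try:
            fb = fit_logistic(Xb, yb)
            nb = fit_logistic(Xb[:, nested_columns], yb)
            deltas[b] = fb.auc - nb.auc
        except FloatingPointError:
            deltas[b] = np.nan
    valid = deltas[np.isfinite(deltas)]
    frac_le0 = float((valid <= 0).mean()) if len(valid) else 1.0
    p = min(1.0, max(2.0 / B, 2.0 * frac_le0))
    full.delta_auc = delta
    full.bootstrap_p = p
    return delta, p, full, nested, deltas
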
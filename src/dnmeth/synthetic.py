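"""Synthetic data generators with known ground truth.

Three generators emulate the study's structure at configurable scale:
negative-binomial region count matrices with planted hypo/hyper DMRs,
annotation tracks with planted TFBS co-location odds, and multi-cohort
clinical tables with risk-graded core-gene methylation, correlated clinical
covariates, and linear eGFR trajectories in planted decline classes.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionCountMatrix
from .annotation import AnnotationBundle
from .cohort import CORE_GENES
from .renal import ckd_epi_egfr

__all__ = [
    "RegionSimConfig",
    "CohortSimConfig",
    "simulate_region_counts",
    "simulate_annotation",
    "simulate_cohort",
    "simulate_prediction_features",
]

CONTIG = "chrS"

ALBUMINURIA_GROUPS = ("healthy", "Normo", "Micro", "Macro", "ESRD")
GROUP_TO_STAGE = {"healthy": "Normo", "Normo": "Normo", "Micro": "Micro",
                  "Macro": "Macro", "ESRD": "ESRD"}
STAGE_ORDER = ("Normo", "Micro", "Macro", "ESRD")
# UACR bands (mg/g) consistent with each albuminuria stage
UACR_BANDS = {"healthy": (1.0, 29.0), "Normo": (1.0, 29.0), "Micro": (30.0, 300.0),
              "Macro": (301.0, 3000.0), "ESRD": (301.0, 5000.0)}
EGFR_GROUP_BASE = {"healthy": 100.0, "Normo": 95.0, "Micro": 80.0,
                   "Macro": 55.0, "ESRD": 12.0}

SLOPE_RANGES = {"none": (-1.0, 0.5), "slow": (-2.8, -1.2), "steep": (-6.0, -3.2)}


@dataclass
class RegionSimConfig:
    """Parameters for the NB region-count generator."""

    n_regions: int = 5000
    n_per_group: int = 10
    group_labels: tuple = ("healthy", "Normo", "Macro", "ESRD")
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    n_hypo_dmrs: int = 0
    n_hyper_dmrs: int = 0
    effect_fold: float = 2.0
    covariate_effects: dict = field(default_factory=dict)
    region_length: int = 510
    region_gap: int = 490
    mean_cv: float = 0.0  # coefficient of variation of per-region baseline means
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be positive")
        if self.n_hypo_dmrs + self.n_hyper_dmrs > self.n_regions:
            raise ValueError("planted DMRs exceed region count")
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 groups")


@dataclass
class CohortSimConfig:
    """Parameters for the multi-cohort clinical-table generator."""

    cohorts: list = field(default_factory=lambda: [
        {"name": "synthetic", "n": {"healthy": 20, "Normo": 40, "Micro": 30,
                                    "Macro": 30, "ESRD": 20}},
    ])
    gene_names: tuple = CORE_GENES
    baseline_meth: float | dict = 85.0
    risk_effect: dict = field(default_factory=lambda: {
        "healthy": 0.0, "Normo": 0.0, "Micro": 4.0, "Macro": 8.0, "ESRD": 14.0})
    covariate_corr: dict = field(default_factory=lambda: {
        "HbA1c": -0.35, "eGFR": 0.35, "UACR": -0.30})
    noise_sd: float = 4.0
    gene_share: float = 0.6  # fraction of noise variance shared across genes
    followup_years: tuple = (4.0, 8.0)
    decline_class_mix: dict = field(default_factory=lambda: {
        "none": 0.5, "slow": 0.3, "steep": 0.2})
    decline_meth_assoc: float = 0.0  # >0 ties steeper decline to lower methylation
    progress_prob: dict = field(default_factory=lambda: {
        "none": 0.08, "slow": 0.30, "steep": 0.60})
    seed: int = 0

    def validate(self) -> None:
        baselines = (self.baseline_meth.values() if isinstance(self.baseline_meth, dict)
                     else [self.baseline_meth])
        for v in baselines:
            if not 0 <= v <= 100:
                raise ValueError("baseline methylation must lie in [0, 100]")
        if abs(sum(self.decline_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("decline_class_mix must sum to 1")
        for name, r in self.covariate_corr.items():
            if abs(r) >= 1:
                raise ValueError(f"unattainable correlation target for {name}: {r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, phi) via gamma-Poisson mixture; phi = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_region_counts(config: RegionSimConfig):
    """Generate an NB region-count matrix with planted DMRs.

    Returns ``(RegionCountMatrix, truth)`` where truth is a DataFrame with
    one row per planted DMR (region index, direction, affected groups, fold).
    Hypo DMRs are assigned cyclically to the case groups (reduced counts in
    the affected group); hyper DMRs gain counts in every case group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, G = config.n_regions, len(config.group_labels)
    n = config.n_per_group
    N = G * n

    step = config.region_length + config.region_gap
    regions = pd.DataFrame({
        "chrom": CONTIG,
        "start": np.arange(R) * step,
        "end": np.arange(R) * step + config.region_length,
    })

    groups = np.repeat(list(config.group_labels), n)
    cell_fracs = rng.dirichlet([8.0, 3.0, 2.0], size=N)
    design = pd.DataFrame({
        "sample": [f"S{i:03d}" for i in range(N)],
        "group": groups,
        "age": np.round(rng.normal(45, 8, N), 1),
        "sex": rng.integers(0, 2, N),
        "cell_frac_lymph": cell_fracs[:, 0],
        "cell_frac_mono": cell_fracs[:, 1],
        "cluster_conc": np.round(rng.normal(200, 15, N), 2),
    }).set_index("sample", drop=False)

    # per-sample multiplicative factor from log-scale covariate effects
    log_factor = np.zeros(N)
    for cov, beta in config.covariate_effects.items():
        col = design[cov].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        log_factor += beta * z
    sample_factor = np.exp(log_factor)

    if config.mean_cv > 0:
        shape = 1.0 / config.mean_cv**2
        mu_region = rng.gamma(shape, config.baseline_mean / shape, size=R)
    else:
        mu_region = np.full(R, config.baseline_mean)

    # group-level fold matrix (regions x groups), 1 = no effect
    fold = np.ones((R, G))
    case_groups = list(config.group_labels[1:])
    n_planted = config.n_hypo_dmrs + config.n_hyper_dmrs
    planted_idx = rng.choice(R, size=n_planted, replace=False)
    hypo_idx = planted_idx[: config.n_hypo_dmrs]
    hyper_idx = planted_idx[config.n_hypo_dmrs:]
    truth_rows = []
    for k, ridx in enumerate(hypo_idx):
        g = case_groups[k % len(case_groups)]
        fold[ridx, config.group_labels.index(g)] = 1.0 / config.effect_fold
        truth_rows.append({"region": int(ridx), "direction": "hypo",
                           "affected_groups": g, "fold": 1.0 / config.effect_fold})
    for ridx in hyper_idx:
        for g in case_groups:
            fold[ridx, config.group_labels.index(g)] = config.effect_fold
        truth_rows.append({"region": int(ridx), "direction": "hyper",
                           "affected_groups": ",".join(case_groups),
                           "fold": config.effect_fold})
    truth = pd.DataFrame(truth_rows, columns=["region", "direction", "affected_groups", "fold"])

    group_idx = np.repeat(np.arange(G), n)
    mean_matrix = mu_region[:, None] * fold[:, group_idx] * sample_factor[None, :]
    counts = _nb_draw(rng, mean_matrix, config.dispersion)

    matrix = RegionCountMatrix(regions=regions, counts=counts,
                               design=design.drop(columns=["sample"]))
    return matrix, truth


def simulate_annotation(
    regions: pd.DataFrame,
    truth: pd.DataFrame,
    n_genes: int = 100,
    n_cgis: int = 50,
    tfbs_factors=("CTCF", "POL2B"),
    planted_or: float = 1.0,
    base_overlap: float = 0.2,
    n_probes: int = 200,
    seed: int = 0,
) -> AnnotationBundle:
    """Generate annotation tracks over the synthetic genome.

    The first factor's intervals are placed so the odds of a hypo-DMR being
    >= 50% covered are ``planted_or`` times those of any other region; the
    remaining factors are null (odds ratio 1). Genes carry strand and exon
    sub-intervals; CpG islands are non-overlapping.
    """
    if planted_or <= 0:
        raise ValueError("planted_or must be positive")
    if not 0 < base_overlap < 1:
        raise ValueError("base_overlap must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genome_len = int(regions["end"].max()) + 10_000

    # non-overlapping genes by slotting the genome
    gene_rows, exon_rows = [], []
    if n_genes > 0:
        slot = genome_len // n_genes
        for i in range(n_genes):
            lo = i * slot
            length = int(rng.integers(max(2000, slot // 10), max(2001, slot // 2)))
            start = int(lo + rng.integers(0, max(1, slot - length)))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"GENE{i:04d}"
            gene_rows.append({"chrom": CONTIG, "start": start, "end": end,
                              "name": name, "strand": strand})
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.integers(start, end, size=2 * n_ex))
            for j in range(n_ex):
                s, e = int(bounds[2 * j]), int(bounds[2 * j + 1])
                if e > s:
                    exon_rows.append({"chrom": CONTIG, "start": s, "end": e,
                                      "name": f"{name}.ex{j}", "gene": name})
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "strand"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "name", "gene"])

    cgi_rows = []
    if n_cgis > 0:
        slot = genome_len // n_cgis
        for i in range(n_cgis):
            length = int(rng.integers(300, 2000))
            start = int(i * slot + rng.integers(0, max(1, slot - length)))
            cgi_rows.append({"chrom": CONTIG, "start": start, "end": start + length,
                             "name": f"CGI{i:04d}"})
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])

    probes = pd.DataFrame({
        "chrom": CONTIG,
        "pos": np.sort(rng.integers(0, genome_len, size=n_probes)),
        "name": [f"cg{i:08d}" for i in range(n_probes)],
    })

    hypo_regions = set(truth.loc[truth["direction"] == "hypo", "region"]) if len(truth) else set()
    odds0 = base_overlap / (1 - base_overlap)
    tfbs = {}
    for fi, factor in enumerate(tfbs_factors):
        odds1 = (planted_or if fi == 0 else 1.0) * odds0
        p1 = odds1 / (1 + odds1)
        rows = []
        for ridx, row in regions.iterrows():
            p = p1 if ridx in hypo_regions else base_overlap
            start, end = int(row["start"]), int(row["end"])
            length = end - start
            if rng.random() < p:
                # cover the whole region: fraction 1 >= any threshold
                rows.append({"chrom": CONTIG, "start": start, "end": end, "name": factor})
            elif rng.random() < 0.3:
                # sub-threshold decoy covering ~30% of the region
                s = start + int(rng.integers(0, max(1, length // 2)))
                rows.append({"chrom": CONTIG, "start": s,
                             "end": s + max(1, int(0.3 * length)), "name": factor})
        tfbs[factor] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    return AnnotationBundle(genes=genes, exons=exons, cpg_islands=cgis,
                            tfbs=tfbs, probes=probes)


def _creatinine_from_egfr(egfr: float, age: float, sex: str) -> float:
    """Invert the CKD-EPI equation by bisection (eGFR is monotone in Scr)."""
    lo, hi = 0.05, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ckd_epi_egfr(mid, age, sex) > egfr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: CohortSimConfig):
    """Generate multi-cohort clinical tables with planted ground truth.

    Per-gene methylation is baseline minus the group's planted risk effect
    plus correlated Gaussian noise, truncated to [0, 100]. HbA1c is drawn via
    a Gaussian copula against the realized mean core methylation so the
    target correlation is hit directly; eGFR and UACR combine the copula
    latent with group structure (UACR stays inside its stage-consistent
    band). eGFR follow-up series are exactly linear with the planted slope.

    Returns ``(table, truth)`` DataFrames indexed by subject.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.gene_names)
    baseline = (config.baseline_meth if isinstance(config.baseline_meth, dict)
                else {g: float(config.baseline_meth) for g in genes})

    rows, truth_rows = [], []
    sid = 0
    classes = list(config.decline_class_mix)
    mix = np.array([config.decline_class_mix[c] for c in classes])

    for cohort in config.cohorts:
        for group, count in cohort["n"].items():
            if group not in ALBUMINURIA_GROUPS:
                raise ValueError(f"unknown albuminuria group {group!r}")
            for _ in range(int(count)):
                rows.append({"subject": f"P{sid:05d}", "cohort": cohort["name"],
                             "group": group})
                sid += 1
    n = len(rows)
    table = pd.DataFrame(rows).set_index("subject", drop=False)

    # methylation: shared subject latent + per-gene noise
    share = np.sqrt(config.gene_share)
    resid = np.sqrt(1 - config.gene_share)
    z_subj = rng.standard_normal(n)
    meth = np.empty((n, len(genes)))
    effects = table["group"].map(config.risk_effect).to_numpy(dtype=float)
    for j, g in enumerate(genes):
        noise = config.noise_sd * (share * z_subj + resid * rng.standard_normal(n))
        meth[:, j] = np.clip(baseline[g] - effects + noise, 0.0, 100.0)
        table[g] = meth[:, j]
    mean_meth = meth.mean(axis=1)
    sd = mean_meth.std()
    m_std = (mean_meth - mean_meth.mean()) / (sd if sd > 0 else 1.0)

    def copula_latent(rho):
        return rho * m_std + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    lat_h = copula_latent(config.covariate_corr.get("HbA1c", 0.0))
    lat_e = copula_latent(config.covariate_corr.get("eGFR", 0.0))
    lat_u = copula_latent(config.covariate_corr.get("UACR", 0.0))

    table["HbA1c"] = np.round(8.3 + 1.3 * lat_h, 2)
    healthy = (table["group"] == "healthy").to_numpy()
    table.loc[healthy, "HbA1c"] = np.round(5.0 + 0.3 * np.abs(lat_h[healthy]), 2)

    egfr_base = table["group"].map(EGFR_GROUP_BASE).to_numpy(dtype=float)
    egfr = np.clip(egfr_base + 12.0 * lat_e, 4.0, 150.0)
    table["eGFR"] = np.round(egfr, 1)

    # UACR inside the stage-consistent band; low methylation -> higher UACR
    u = stats.norm.cdf(-lat_u)
    lo = table["group"].map(lambda g: UACR_BANDS[g][0]).to_numpy()
    hi = table["group"].map(lambda g: UACR_BANDS[g][1]).to_numpy()
    table["UACR"] = np.round(lo * (hi / lo) ** u, 1)

    table["age"] = np.round(np.clip(rng.normal(45, 10, n), 18, 80), 1)
    table["sex"] = np.where(rng.random(n) < 0.5, "F", "M")
    table["diabetes_duration"] = np.where(
        healthy, 0.0, np.round(np.clip(rng.normal(30, 8, n), 1, 60), 1))
    table["smoking"] = rng.integers(0, 2, n) * (rng.random(n) < 0.5)
    table["SBP"] = np.round(rng.normal(135, 15, n), 1)
    table["serum_creatinine"] = [
        round(_creatinine_from_egfr(e, a, s), 3)
        for e, a, s in zip(table["eGFR"], table["age"], table["sex"])
    ]
    table["esrd"] = (table["group"] == "ESRD").astype(int)
    table["albuminuria_baseline"] = table["group"].map(GROUP_TO_STAGE)

    # planted decline classes, optionally tied to low methylation
    if config.decline_meth_assoc > 0:
        a = config.decline_meth_assoc
        score = -a * m_std + rng.standard_normal(n)
        order = np.argsort(score)  # low score -> mild class
        bounds = np.cumsum(np.round(mix * n).astype(int))
        decline = np.empty(n, dtype=object)
        prev = 0
        for cls, b in zip(classes, bounds):
            decline[order[prev:min(b, n)]] = cls
            prev = min(b, n)
        decline[order[prev:]] = classes[-1]
    else:
        decline = rng.choice(classes, size=n, p=mix / mix.sum())

    slopes = np.empty(n)
    spans = rng.uniform(*config.followup_years, size=n)
    fu_times, fu_egfr, last_stage = [], [], []
    stage_idx = {s: i for i, s in enumerate(STAGE_ORDER)}
    for i in range(n):
        lo_s, hi_s = SLOPE_RANGES[decline[i]]
        slope = rng.uniform(lo_s, hi_s)
        slopes[i] = slope
        T = spans[i]
        e0 = float(table["eGFR"].iloc[i])
        # keep the whole linear trajectory above the floor so the planted
        # class is exactly recoverable from the endpoints
        e0 = max(e0, 8.0 - slope * T)
        times = np.arange(0.0, T, 1.0)
        # keep the serialized grid strictly increasing at 2-decimal precision
        if T - times[-1] < 0.05:
            times[-1] = T
        else:
            times = np.append(times, T)
        series = e0 + slope * times
        fu_times.append(",".join(f"{t:.2f}" for t in times))
        fu_egfr.append(",".join(f"{v:.2f}" for v in series))

        base_stage = table["albuminuria_baseline"].iloc[i]
        j = stage_idx[base_stage]
        progressed = (j < len(STAGE_ORDER) - 1
                      and rng.random() < config.progress_prob[decline[i]])
        last_stage.append(STAGE_ORDER[j + 1] if progressed else base_stage)
    table["followup_times"] = fu_times
    table["followup_egfr"] = fu_egfr
    table["albuminuria_last"] = last_stage

    truth = pd.DataFrame({
        "subject": table["subject"],
        "group": table["group"],
        "decline_class": decline,
        "slope": slopes,
        "progressor": [stage_idx[b] < stage_idx[l] for b, l in
                       zip(table["albuminuria_baseline"], last_stage)],
    }).set_index("subject", drop=False)
    return table, truth


def simulate_prediction_features(
    n: int,
    auc_nested: float = 0.65,
    auc_full: float = 0.75,
    prevalence: float = 0.5,
    n_clinical: int = 5,
    seed: int = 0,
):
    """Binormal generator with controlled nested/full true AUCs.

    Outcomes are Bernoulli(prevalence); each clinical feature shifts by
    ``d_c / sqrt(n_clinical)`` in cases and the index feature by
    ``sqrt(d_total^2 - d_c^2)``, where ``d = sqrt(2) * Phi^-1(AUC)`` so the
    optimal linear score attains the requested true AUC with and without the
    index. Returns ``(X, nested_columns, y, feature_names)`` with the index
    as the last column.
    """
    if not 0.5 <= auc_nested <= auc_full < 1:
        raise ValueError("need 0.5 <= auc_nested <= auc_full < 1")
    rng = np.random.default_rng(seed)
    d_c = np.sqrt(2.0) * stats.norm.ppf(auc_nested)
    d_t = np.sqrt(2.0) * stats.norm.ppf(auc_full)
    d_m = np.sqrt(max(d_t**2 - d_c**2, 0.0))
    y = (rng.random(n) < prevalence).astype(float)
    X = rng.standard_normal((n, n_clinical + 1))
    X[:, :n_clinical] += np.outer(y, np.full(n_clinical, d_c / np.sqrt(n_clinical)))
    X[:, n_clinical] += y * d_m
    names = ["DM_duration", "HbA1c", "UACR", "smoking", "SBP"][:n_clinical]
    names += [f"clin{j}" for j in range(len(names), n_clinical)]
    names.append("meth_index")
    return X, list(range(n_clinical)), y, names
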
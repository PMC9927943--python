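"""TFBS overlap enrichment among hypo- vs hyper-methylated DMRs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnrichmentResult", "overlap_fraction", "tfbs_odds_ratio_test", "enrichment_scan"]


@dataclass
class EnrichmentResult:
    factor: str
    table: tuple  # (hypo_overlap, hypo_no, hyper_overlap, hyper_no)
    hypo_fraction: float
    hyper_fraction: float
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    testable: bool = True


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge sorted-or-not intervals into a disjoint union."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def overlap_fraction(dmrs, tfbs: pd.DataFrame, min_frac: float = 0.5):
    """Per-DMR overlap flags against one factor's intervals.

    A DMR overlaps iff the base pairs of the DMR covered by the merged union
    of the factor's intervals, divided by DMR length, reach ``min_frac``
    (inclusive). Returns ``(flags, coverages)`` as numpy arrays.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    by_chrom: dict = {}
    if len(tfbs):
        for chrom, sub in tfbs.groupby("chrom"):
            by_chrom[chrom] = _merge_intervals(sub[["start", "end"]].to_numpy())
    flags = []
    covs = []
    for chrom, start, end in dmrs:
        start, end = int(start), int(end)
        length = end - start
        if length <= 0:
            raise ValueError("zero-length DMR")
        covered = 0
        for s, e in by_chrom.get(chrom, ()):  # disjoint after merge
            covered += max(0, min(end, e) - max(start, s))
        frac = covered / length
        covs.append(frac)
        flags.append(frac >= min_frac)
    return np.asarray(flags, dtype=bool), np.asarray(covs, dtype=float)


def tfbs_odds_ratio_test(hypo_flags, hyper_flags, factor: str = "") -> EnrichmentResult:
    """Odds-ratio test of overlap between hypo- and hyper-methylated DMRs.

    2x2 table (hypo/hyper x overlap/no-overlap); OR = (a*d)/(b*c) with a
    Haldane-Anscombe +0.5 applied iff any cell is zero; two-sided p from
    Fisher's exact test; 95% CI from the log-OR normal approximation.
    """
    hypo = np.asarray(hypo_flags, dtype=bool)
    hyper = np.asarray(hyper_flags, dtype=bool)
    if len(hypo) == 0 or len(hyper) == 0:
        raise ValueError("both DMR classes must be non-empty")
    a = int(hypo.sum())
    b = int(len(hypo) - a)
    c = int(hyper.sum())
    d = int(len(hyper) - c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    oratio = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(oratio)
    return EnrichmentResult(
        factor=factor,
        table=(a, b, c, d),
        hypo_fraction=a / len(hypo),
        hyper_fraction=c / len(hyper),
        odds_ratio=float(oratio),
        p_value=min(p, 1.0),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
    )


def enrichment_scan(dmrs, directions, bundle_tfbs: dict, min_frac: float = 0.5) -> list[EnrichmentResult]:
    """Run overlap + odds-ratio testing for every factor.

    ``dmrs`` is a sequence of (chrom, start, end); ``directions`` the matching
    'hypo'/'hyper' labels. Factors without intervals are flagged untestable
    with fractions 0.
    """
    if not bundle_tfbs:
        raise ValueError("need at least one factor")
    directions = np.asarray(directions)
    hypo_idx = directions == "hypo"
    hyper_idx = directions == "hyper"
    dmr_list = list(dmrs)
    results = []
    for factor, intervals in bundle_tfbs.items():
        if intervals is None or not len(intervals):
            results.append(
                EnrichmentResult(
                    factor=factor, table=(0, int(hypo_idx.sum()), 0, int(hyper_idx.sum())),
                    hypo_fraction=0.0, hyper_fraction=0.0, odds_ratio=float("nan"),
                    p_value=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                    testable=False,
                )
            )
            continue
        flags, _ = overlap_fraction(dmr_list, intervals, min_frac=min_frac)
        results.append(
            tfbs_odds_ratio_test(flags[hypo_idx], flags[hyper_idx], factor=factor)
        )
    return results
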
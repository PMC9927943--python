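"""Genomic and CpG-context annotation of regions.

Classifies regions by gene context (promoter/exon/intron/intergenic) and CpG
context (CGI/shore/shelf/open sea), profiles signed distances to the nearest
TSS, counts array probes within nested distance windows of DMRs, and runs
hypergeometric gene-set over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import bh_qvalues

__all__ = [
    "AnnotationBundle",
    "FeatureLabel",
    "classify_region",
    "tss_distance_profile",
    "probe_proximity",
    "geneset_enrichment",
]

SHORE_BP = 1_000
SHELF_BP = 5_000
DEFAULT_PROMOTER_BP = 2_000

GENE_CONTEXTS = ("promoter", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("CGI", "shore", "shelf", "open_sea")
# precedence for the single primary label
_PRECEDENCE = ("CGI", "shore", "shelf", "promoter", "exon", "intron", "intergenic")


@dataclass
class AnnotationBundle:
    """Interval tracks on one or more contigs, all 0-based half-open.

    ``genes`` needs columns chrom/start/end/name/strand (BED6-like); TSS is
    ``start`` on '+' genes and ``end - 1`` on '-' genes. ``exons`` carries a
    ``gene`` column naming its parent. ``tfbs`` maps factor label -> interval
    DataFrame. ``probes`` has chrom/pos/name.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    cpg_islands: pd.DataFrame
    tfbs: dict = field(default_factory=dict)
    probes: pd.DataFrame | None = None
    extra_tracks: dict = field(default_factory=dict)
    promoter_bp: int = DEFAULT_PROMOTER_BP

    def __post_init__(self) -> None:
        for name, df in [("genes", self.genes), ("exons", self.exons), ("cpg_islands", self.cpg_islands)]:
            if len(df) and (df["start"] >= df["end"]).any():
                raise ValueError(f"{name}: intervals must satisfy start < end")

    def contigs(self) -> set:
        out = set(self.genes["chrom"]) | set(self.cpg_islands["chrom"])
        if self.probes is not None:
            out |= set(self.probes["chrom"])
        return out

    def tss_table(self) -> pd.DataFrame:
        """Per-gene TSS position honoring strand."""
        g = self.genes
        tss = np.where(g["strand"] == "-", g["end"].to_numpy() - 1, g["start"].to_numpy())
        return pd.DataFrame({"chrom": g["chrom"].to_numpy(), "tss": tss, "strand": g["strand"].to_numpy()})


@dataclass(frozen=True)
class FeatureLabel:
    gene_context: str
    cpg_context: str

    @property
    def primary(self) -> str:
        candidates = {self.gene_context, self.cpg_context}
        for label in _PRECEDENCE:
            if label in candidates:
                return label
        return "intergenic"


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def _point_in_intervals(pos: int, chrom, df: pd.DataFrame) -> bool:
    if not len(df):
        return False
    sel = df[df["chrom"] == chrom]
    return bool(((sel["start"] <= pos) & (pos < sel["end"])).any())


def _distance_to_intervals(pos: int, chrom, df: pd.DataFrame) -> float:
    """0 if inside an interval, else bp gap to the nearest edge; inf if none."""
    sel = df[df["chrom"] == chrom]
    if not len(sel):
        return np.inf
    start = sel["start"].to_numpy()
    end = sel["end"].to_numpy()
    inside = (start <= pos) & (pos < end)
    if inside.any():
        return 0.0
    d = np.where(pos < start, start - pos, pos - (end - 1))
    return float(d.min())


def classify_region(region, bundle: AnnotationBundle) -> FeatureLabel:
    """Assign gene-context and CpG-context labels from the region midpoint.

    CpG context: CGI if the midpoint lies inside an island, shore within 1 kb
    of an island edge, shelf within 1-5 kb, else open sea. Gene context:
    promoter if within the TSS window, exon if inside an exon, intron if
    inside a gene body but no exon, else intergenic.
    """
    chrom, start, end = region[0], int(region[1]), int(region[2])
    known = bundle.contigs()
    if known and chrom not in known:
        raise KeyError(f"unknown contig {chrom!r}")
    mid = _midpoint(start, end)

    d = _distance_to_intervals(mid, chrom, bundle.cpg_islands)
    if d == 0:
        cpg = "CGI"
    elif d <= SHORE_BP:
        cpg = "shore"
    elif d <= SHELF_BP:
        cpg = "shelf"
    else:
        cpg = "open_sea"

    gene_ctx = "intergenic"
    tss = bundle.tss_table()
    sel = tss[tss["chrom"] == chrom]
    in_promoter = len(sel) and (np.abs(sel["tss"].to_numpy() - mid) <= bundle.promoter_bp).any()
    if in_promoter:
        gene_ctx = "promoter"
    elif _point_in_intervals(mid, chrom, bundle.exons):
        gene_ctx = "exon"
    elif _point_in_intervals(mid, chrom, bundle.genes):
        gene_ctx = "intron"
    return FeatureLabel(gene_context=gene_ctx, cpg_context=cpg)


def tss_distance_profile(dmrs, genes: pd.DataFrame, bin_width: int = 1_000, max_distance: int = 10_000):
    """Histogram of signed DMR-midpoint-to-nearest-TSS distances.

    Distance = (midpoint - TSS) * strand sign, upstream negative. Returns
    ``(bin_edges, counts, n_excluded)``; DMRs whose nearest TSS lies beyond
    ``max_distance`` are excluded and counted separately.
    """
    if not len(genes):
        raise ValueError("no genes provided")
    tss_pos = np.where(genes["strand"] == "-", genes["end"].to_numpy() - 1, genes["start"].to_numpy())
    sign = np.where(genes["strand"] == "-", -1, 1)
    chroms = genes["chrom"].to_numpy()

    edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_excluded = 0
    for chrom, start, end in dmrs:
        mid = _midpoint(int(start), int(end))
        on = chroms == chrom
        if not on.any():
            n_excluded += 1
            continue
        raw = mid - tss_pos[on]
        j = int(np.argmin(np.abs(raw)))
        d = raw[j] * sign[on][j]
        if abs(d) > max_distance:
            n_excluded += 1
            continue
        idx = min(int((d + max_distance) // bin_width), len(counts) - 1)
        counts[idx] += 1
    return edges, counts, n_excluded


def probe_proximity(probes: pd.DataFrame, dmrs, windows) -> dict:
    """Count probes within each distance window of the nearest DMR.

    A probe at distance 0 lies inside a DMR (position in [start, end)).
    Counts are cumulative over the ascending ``windows``; window 0 counts
    direct overlaps only.
    """
    windows = list(windows)
    if any(w < 0 for w in windows):
        raise ValueError("windows must be non-negative")
    if windows != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    dmr_list = [(c, int(s), int(e)) for c, s, e in dmrs]
    dists = []
    for _, row in probes.iterrows():
        pos, chrom = int(row["pos"]), row["chrom"]
        best = np.inf
        for c, s, e in dmr_list:
            if c != chrom:
                continue
            if s <= pos < e:
                best = 0.0
                break
            best = min(best, s - pos if pos < s else pos - (e - 1))
        dists.append(best)
    dists = np.asarray(dists, dtype=float)
    return {w: int((dists <= w).sum()) for w in windows}


def geneset_enrichment(selected, universe, gene_sets: dict, fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` genes per gene set.

    Upper-tail hypergeometric p per set, Benjamini-Hochberg q across sets,
    ``enriched`` iff q < fdr. ``selected`` must be a subset of ``universe``.
    """
    selected = set(selected)
    universe = set(universe)
    missing = selected - universe
    if missing:
        raise ValueError(f"selected genes absent from universe: {sorted(missing)[:5]}")
    N = len(universe)
    n = len(selected)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            raise ValueError(f"gene set {name!r} is empty within the universe")
        K = len(members)
        k = len(selected & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["enriched"] = out["q"] < fdr
    return out
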
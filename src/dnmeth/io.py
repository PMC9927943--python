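"""Readers and writers for the on-disk formats.

Conventions: genomic coordinates are 0-based half-open everywhere (BED);
TSV files are tab-separated UTF-8 with '#'-prefixed header/provenance lines;
missing numeric values are empty fields; truth tables and result summaries
are JSON; configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotationBundle
from .regions import RegionCountMatrix

__all__ = [
    "load_config",
    "provenance_lines",
    "write_region_counts",
    "read_region_counts",
    "write_bed",
    "read_bed",
    "write_cohort_table",
    "read_cohort_table",
    "write_annotation_bundle",
    "read_annotation_bundle",
    "write_json",
    "read_json",
    "parse_followup",
]


def load_config(path) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: dict | None = None, seed: int | None = None) -> list[str]:
    from . import __version__

    lines = [f"#dnmeth_version={__version__}"]
    if seed is not None:
        lines.append(f"#seed={seed}")
    if config is not None:
        lines.append(f"#config_hash={config_hash(config)}")
    return lines


def _write_tsv(df: pd.DataFrame, path, header_lines=()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    columns = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                columns = line[1:].rstrip("\n").split("\t")
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, header=None)
    if columns is not None and len(columns) == df.shape[1]:
        df.columns = columns
    return df


def write_region_counts(matrix: RegionCountMatrix, counts_path, design_path,
                        header_lines=()) -> None:
    df = matrix.regions[["chrom", "start", "end"]].copy()
    for j, sample in enumerate(matrix.design.index):
        df[str(sample)] = matrix.counts[:, j]
    _write_tsv(df, counts_path, header_lines)
    design = matrix.design.reset_index(names="sample")
    _write_tsv(design, design_path, header_lines)


def read_region_counts(counts_path, design_path) -> RegionCountMatrix:
    df = _read_tsv(counts_path)
    design = _read_tsv(design_path).set_index("sample")
    regions = df[["chrom", "start", "end"]].copy()
    regions["start"] = regions["start"].astype(int)
    regions["end"] = regions["end"].astype(int)
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    missing = [s for s in design.index.astype(str) if s not in sample_cols]
    if missing:
        raise ValueError(f"design samples missing from count matrix: {missing[:5]}")
    counts = df[list(design.index.astype(str))].to_numpy(dtype=np.int64)
    return RegionCountMatrix(regions=regions, counts=counts, design=design)


def write_bed(df: pd.DataFrame, path, header_lines=()) -> None:
    """Write BED6 (chrom start end name score strand); missing columns are
    filled with '.'/0."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["name"] if "name" in df else ".",
        "score": df["score"] if "score" in df else 0,
        "strand": df["strand"] if "strand" in df else ".",
    })
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3-6; validates coordinates and names the offending line on error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval start={start} end={end}"
                )
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else ".",
                "score": float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0,
                "strand": parts[5] if len(parts) > 5 else ".",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# Column dictionary for cohort tables (written alongside the TSV):
COHORT_COLUMNS = {
    "subject": "subject identifier",
    "cohort": "cohort name",
    "group": "albuminuria group: healthy/Normo/Micro/Macro/ESRD",
    "HbA1c": "glycated hemoglobin, % NGSP",
    "eGFR": "estimated GFR, mL/min/1.73m2",
    "UACR": "urinary albumin-to-creatinine ratio, mg/g",
    "age": "age, years",
    "sex": "F/M",
    "diabetes_duration": "years since diabetes diagnosis",
    "smoking": "current smoker, 0/1",
    "SBP": "systolic blood pressure, mmHg",
    "serum_creatinine": "serum creatinine, mg/dL",
    "esrd": "dialysis or kidney transplant, 0/1",
    "albuminuria_baseline": "albuminuria stage at baseline",
    "albuminuria_last": "albuminuria stage at last follow-up",
    "followup_times": "comma-separated follow-up times, years",
    "followup_egfr": "comma-separated eGFR at follow-up times",
}


def write_cohort_table(table: pd.DataFrame, path, header_lines=()) -> None:
    _write_tsv(table.reset_index(drop=True), path, header_lines)
    dict_path = Path(path).with_suffix(".columns.json")
    known = {c: COHORT_COLUMNS.get(c, "per-gene methylation, %") for c in table.columns}
    dict_path.write_text(json.dumps(known, indent=2) + "\n")


def read_cohort_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "subject" in df.columns:
        df = df.set_index("subject", drop=False)
    return df


def parse_followup(row) -> list[tuple[float, float]]:
    times = [float(t) for t in str(row["followup_times"]).split(",")]
    egfr = [float(v) for v in str(row["followup_egfr"]).split(",")]
    if len(times) != len(egfr):
        raise ValueError("follow-up times and eGFR series differ in length")
    return list(zip(times, egfr))


def write_annotation_bundle(bundle: AnnotationBundle, outdir, header_lines=()) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(bundle.genes, outdir / "genes.bed", header_lines)
    write_bed(bundle.exons.assign(name=bundle.exons.get("gene", ".")),
              outdir / "exons.bed", header_lines)
    write_bed(bundle.cpg_islands, outdir / "cpg_islands.bed", header_lines)
    for factor, df in bundle.tfbs.items():
        write_bed(df, outdir / f"tfbs_{factor}.bed", header_lines)
    if bundle.probes is not None:
        probes = bundle.probes.assign(start=bundle.probes["pos"],
                                      end=bundle.probes["pos"] + 1)
        write_bed(probes, outdir / "probes.bed", header_lines)


def read_annotation_bundle(outdir) -> AnnotationBundle:
    outdir = Path(outdir)
    genes = read_bed(outdir / "genes.bed")
    exons = read_bed(outdir / "exons.bed").rename(columns={"name": "gene"})
    exons["name"] = exons["gene"]
    cgis = read_bed(outdir / "cpg_islands.bed")
    tfbs = {}
    for path in sorted(outdir.glob("tfbs_*.bed")):
        factor = path.stem[len("tfbs_"):]
        tfbs[factor] = read_bed(path)
    probes = None
    probe_path = outdir / "probes.bed"
    if probe_path.exists():
        bed = read_bed(probe_path)
        probes = pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"],
                               "name": bed["name"]})
    return AnnotationBundle(genes=genes, exons=exons, cpg_islands=cgis,
                            tfbs=tfbs, probes=probes)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
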
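# dnmeth

Leukocyte-methylation analysis of diabetic-nephropathy (DN) risk, as a
reusable, tested pipeline with two arms:

1. **Region arm** — region-level differential methylation from methyl-capture
   count matrices: log-CPM normalization, common NB dispersion estimation, a
   negative-binomial exact test for all pairwise group contrasts, DMR calling
   at a configurable threshold, profile clustering (correlation distance,
   average linkage), sample PCA, genomic/CpG-context annotation (promoter /
   exon / intron / intergenic; CGI / shore ±1 kb / shelf 1–5 kb / open sea),
   TSS-distance profiles, array-probe proximity windows, gene-set
   over-representation, and TFBS overlap odds-ratio enrichment (≥50% DMR
   coverage, Fisher's exact test).

2. **Clinical arm** — a core-gene methylation index (PC1-loading weights,
   rescaled so a reference group's mean is 100%), Mann-Whitney group
   contrasts and Pearson covariate correlations, CKD-EPI eGFR, albuminuria
   staging, KDIGO risk categorization, eGFR-decline classification
   (none / slow / steep by endpoint slope), albuminuria-progression flags,
   logistic prediction models with ROC AUC and bootstrap ΔAUC, and
   sample-size-weighted median-difference meta-analysis with Fisher's
   combined probability test.

A third module, `dnmeth.synthetic`, generates all inputs with known ground
truth (NB region counts with planted hypo/hyper DMRs, annotation tracks with
planted TFBS co-location odds, multi-cohort clinical tables with risk-graded
methylation, correlated covariates, and linear eGFR trajectories in planted
decline classes), so every stage is testable without external data.

## CLI

All subcommands accept `--config cfg.yaml --seed N --out dir/ --log-level L`.

```sh
# region arm
dnmeth simulate regions  --config cfg.yaml --seed 1 --out sim/
dnmeth simulate annotation --regions sim/region_counts.tsv \
    --design sim/design.tsv --truth sim/truth.json --seed 1 --out tracks/
dnmeth dmr      --counts sim/region_counts.tsv --design sim/design.tsv \
    --alpha 0.01 --seed 1 --out dmr/
dnmeth annotate --dmrs dmr/dmrs.bed --tracks tracks/ --seed 1 --out annot/
dnmeth enrich   --dmrs dmr/dmrs.bed --tracks tracks/ --min-frac 0.5 \
    --seed 1 --out enrich/

# clinical arm
dnmeth simulate cohort --config cfg.yaml --seed 1 --out cohort/
dnmeth index --cohort cohort/cohort.tsv --reference-group Normo \
    --seed 1 --out index/
dnmeth risk  --cohort cohort/cohort.tsv --seed 1 --out risk/
dnmeth progression --cohort cohort/cohort.tsv \
    --index index/methylation_index.tsv --seed 1 --out prog/
dnmeth meta  --cohort cohort/cohort.tsv --index index/methylation_index.tsv \
    --risk risk/kdigo_risk.tsv --seed 1 --out meta/
```

Formats: BED6 for annotation tracks and DMR output (score = −log10 p × 100,
capped), TSV for count matrices and cohort tables (tab-separated, UTF-8,
`#`-prefixed header/provenance lines), JSON for truth tables and result
summaries, YAML for configuration. Coordinates are 0-based half-open
everywhere. Every output carries a provenance header (package version, seed,
config hash). Cohort TSVs get a sibling `.columns.json` column dictionary.

## Layout

| module | contents |
|---|---|
| `dnmeth.synthetic` | ground-truth generators (regions, annotation, cohorts, prediction features) |
| `dnmeth.regions` | log-CPM, NB dispersion, NB exact test, DMR calling, clustering, PCA |
| `dnmeth.annotation` | gene/CpG-context classification, TSS profiles, probe proximity, gene sets |
| `dnmeth.tfbs` | TFBS overlap fractions and odds-ratio enrichment |
| `dnmeth.cohort` | methylation index, Mann-Whitney, Pearson correlation |
| `dnmeth.renal` | CKD-EPI eGFR, albuminuria staging, KDIGO risk matrix |
| `dnmeth.progression` | eGFR slope/decline classes, logistic models, AUC, bootstrap ΔAUC |
| `dnmeth.meta` | median differences, weighted pooling, Fisher's combined test |
| `dnmeth.io`, `dnmeth.cli` | formats, provenance, and the `dnmeth` command |
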
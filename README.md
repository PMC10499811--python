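# lewypanel

A tested, reusable pipeline for CSF proximity-extension-assay (PEA/NPX)
biomarker discovery: NPX quality control and batch bridging, nested-linear-model
differential abundance, UpSet subset partitioning, elastic-net logistic panel
selection with stability analysis and ridge refit, resampling-based ROC
evaluation, Passing–Bablok method harmonization, and hypergeometric gene-set
enrichment with kappa clustering — exercised end-to-end on a synthetic cohort
generator that emulates a three-group (CON/DLB/AD) study design with planted
ground truth.

## Layout

| module | what it does |
| --- | --- |
| `lewypanel.npx` | `NPXMatrix` container; long-format CSV/TSV I/O; ≥85 % detectability filter (below-LOD values kept raw); bridging-sample reference normalization; replicate-assay Spearman correlations |
| `lewypanel.cohort` | `CohortDesign` / `generate_cohort`: three-group cohorts with effect classes (`dlb_unique`, `general_dementia`, `shared_divergent`, `ad_specific`, `null`), age/sex confounding, batch offsets + 16 bridging samples, per-assay LOD censoring, and a `TruthTable` for recovery tests |
| `lewypanel.diff` | per-protein nested linear models (protein ~ age + sex + group, exact F-test), BH-FDR, volcano-ready contrast tables; logistic variant behind a flag |
| `lewypanel.upset` | partition of nominally significant DLB-vs-CON proteins by DLB-vs-AD / AD-vs-CON behavior; counts, percentages, bootstrap direction summaries |
| `lewypanel.panel` | hand-rolled elastic-net penalized logistic solver (covariates unpenalized, KKT-checked), dual (alpha × marker-cap) grid with balanced 10-fold CV of the held-out likelihood, fold-based selection proportions, ridge refit (penalty 0.1), serializable `PanelModel` |
| `lewypanel.evaluate` | rank-based AUC + ROC curves, stratified bootstrap CIs, repeated 5-fold CV AUC with percentile CIs, DeLong paired comparison, frozen-model external validation, partial Spearman correlations, stage ANOVA |
| `lewypanel.harmonize` | Passing–Bablok regression (shifted median of pairwise slopes) and the shipped Luminex→Innotest coefficient table |
| `lewypanel.enrich` | GMT reader, upper-tail hypergeometric enrichment (p < 0.01, count ≥ 3, enrichment factor > 1.5), Cohen-kappa average-linkage term clustering (cut at similarity 0.3) |
| `lewypanel.config` / `lewypanel.cli` | YAML `RunConfig`, end-to-end `run_pipeline`, `lewypanel` CLI |

## CLI

```bash
lewypanel simulate --seed 1 --out runs/sim          # synthetic cohort + truth
lewypanel qc --npx runs/sim/npx.csv --reference-batch R1 --out runs/npx_qc.csv
lewypanel diff --npx runs/sim/npx.csv --metadata runs/sim/metadata.csv \
    --contrast DLB_vs_CON --out runs/dlb_con.tsv
lewypanel upset --dlb-con runs/dlb_con.tsv --dlb-ad ... --ad-con ... --out runs/upset
lewypanel panel --npx ... --metadata ... --contrast DLB_vs_AD --out runs/panel
lewypanel harmonize --pairs pairs.csv
lewypanel enrich --query q.txt --background bg.txt --gmt sets.gmt --out enrich.tsv
lewypanel run-all --seed 20230913 --out runs/r1     # full pipeline, manifest included
```

Exit codes: 0 ok, 1 data error, 2 usage error. Every artifact records the
seed; the same config + seed reproduces result tables byte-identically.

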
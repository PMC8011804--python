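# methcovar

Cross-cell-type DNA methylation covariation analysis for interpreting
whole-blood EWAS findings.

Whole-blood methylation profiles are proportion-weighted mixtures of the
profiles of the constituent blood cell types. This package quantifies, per
CpG site, how inter-individual variation in whole blood relates to
variation in five purified cell types (monocytes, granulocytes, CD4+ T
cells, CD8+ T cells, B cells) and two epithelial tissues (buccal, nasal):

- **`synthetic_data`** — a twin-cohort mixture simulator (MZ/DZ structure,
  genetic / environmental / single-cell-type variance classes, Dirichlet
  cell proportions) with full ground truth, so every downstream stage is
  testable without any external download.
- **`profiling`** — methylation-band summaries, variable-site flags,
  top-variable-site selection, hierarchical clustering order, PCA.
- **`differential`** — per-site mixed-effects ANOVA (sample type fixed
  effect; nested family/individual random intercepts; REML with
  Satterthwaite degrees of freedom) for differentially methylated
  positions, whole-blood-referenced contrasts, sharing classification.
- **`variability`** — per-type dispersion, k-group Levene scan for
  differentially variable positions, SD-correlation summaries.
- **`covariation`** — per-site single-cell-type variance explained
  (100·r²) and the joint five-cell-type OLS R², with dominant-driver
  counts and stratified summaries (bands, variability, A/E heritability
  annotation, mQTL flag).
- **`characteristic`** — "characteristic scores": mean-center within cell
  type, then a one-sided (larger-variance) Levene test of each cell type
  against the pooled other four; classification of single-cell-type
  driver sites; EWAS catalog annotation and per-trait enrichment fold
  changes.
- **`predictors`** — coefficient-based predictors (epigenetic age with the
  piecewise log/linear transform, smoking-type scores), cross-sample-type
  comparisons and within-individual ranges.
- **`mixedlm`** — the shared nested-random-intercept REML engine
  (validated against `statsmodels.MixedLM` in the test suite).

## CLI

A single `methcovar` executable with subcommands; every command takes
`--config` (YAML), `--seed`, `--threads`, `--log-level`, writes TSV output
plus a JSON run-metadata sidecar (`<out>.meta.json`).

```bash
# generate a synthetic twin cohort with ground truth
methcovar simulate --config sim.yaml --seed 7 --out-dir simdata/

# scans (defaults: alpha 9e-8 for DMP/characteristic, 9.42e-8 for DVP)
methcovar scan-dmp  --beta simdata/beta.tsv --samples simdata/samples.csv --out dmp.tsv
methcovar scan-dvp  --beta simdata/beta.tsv --samples simdata/samples.csv --out dvp.tsv
methcovar covary    --beta simdata/beta.tsv --samples simdata/samples.csv \
                    --out covar.tsv --summary covar_summary.json
methcovar characteristic --beta simdata/beta.tsv --samples simdata/samples.csv --out scores.tsv
methcovar annotate-ewas --scores scores.tsv --hits ewas.tsv \
                    --out annotated.tsv --enrichment enrich.tsv

# coefficient predictors (coefficient tables are user-supplied inputs)
methcovar predict --beta simdata/beta.tsv --samples simdata/samples.csv \
                  --model coefs.csv --intercept 0.696 --transform horvath_age --out preds.tsv
```

## File formats

- **Beta matrix** — TSV; first column `site_id`, one column per sample;
  values in [0, 1], `NA` for missing.
- **Sample sheet** — CSV with `sample_id, individual_id, family_id,
  sample_type[, zygosity, sex]`; sample types are `whole_blood, buccal,
  nasal, monocytes, granulocytes, cd4t, cd8t, bcell`.
- **Coefficient table** — CSV with `site_id, weight`; intercept/transform
  via flags.
- **EWAS catalog** — TSV with `site_id, trait, p_value, tissue, study_id`.
- **Annotation table** — TSV with `site_id` and optional `A`, `E`
  (variance fractions in [0, 1]) and `has_mqtl` columns.
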
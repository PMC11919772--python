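# methvar

Case-control DNA methylation **variance** and mean-effect EWAS toolkit:
per-cohort association testing on covariate-residualised beta values,
empirical-null bias/inflation correction, cross-cohort meta-analysis,
regional aggregation, and downstream enrichment / epigenetic-covariance
analyses — plus a synthetic multi-cohort generator with known ground truth
for end-to-end validation.

## What it does

1. **Simulation** (`methvar.sim`) — latent-logistic generator producing
   multi-cohort beta matrices with covariate/batch structure and planted
   group-variance ratios and latent mean shifts; manifest-style probe
   annotation; external-catalog and expression-table fixtures.
2. **QC** (`methvar.qc`) — sample filters (detection-P failure fraction,
   median intensity, sex concordance), probe filters (detection, blacklist
   flags), and cohort demographics (continuity-corrected 2×2 sex χ²,
   Welch t on epigenetic age).
3. **Association** (`methvar.association`) — OLS residualisation on a shared
   covariate design; vectorised Levene (Brown–Forsythe), Bartlett and
   Fligner–Killeen tests with signed Z-scores (positive = more dispersed in
   cases); per-probe mean-effect EWAS (β, SE, P).
4. **Empirical null** (`methvar.empirical_null`) — Gibbs-sampled
   three-component Gaussian mixture on signed Z-scores; the central
   component's location/scale give the bias and inflation used to rescale
   statistics ((z − bias)/inflation) or effect/SE pairs.
5. **Meta-analysis** (`methvar.meta`) — √n-weighted Stouffer combination of
   variance Z-scores, IVW fixed/random effects (DerSimonian–Laird τ²) for
   mean effects, BH FDR + Bonferroni multiplicity, VMP/DMP classification.
6. **Regions** (`methvar.regions`) — seed-and-extend aggregation with
   Stouffer–Liptak combination under an empirical distance-correlation model
   and Sidak correction (reported regions: ≥2 probes, P_Sidak < 0.05).
7. **Downstream** (`methvar.downstream`) — Fisher's exact enrichment in
   tissue/genomic/disorder sets (direction-stratified, Haldane–Anscombe OR),
   top-fraction tissue-enriched set construction, per-trait epigenetic
   covariance against external EWAS catalogs (≥10-probe rule).
8. **Pipeline + IO** (`methvar.pipeline`, `methvar.io`, `methvar.cli`) —
   YAML-configured end-to-end orchestration with sex-stratified reruns,
   provenance headers, and a manifest of per-stage counts.

## CLI

```sh
methvar simulate --config sim.yaml --out data/
methvar qc --beta data/cohort0_beta.tsv --detp data/cohort0_detp.tsv \
    --samples data/cohort0_samples.csv --annotation data/annotation.csv \
    --out qc/
methvar ewas --beta data/cohort0_beta.tsv --samples data/cohort0_samples.csv \
    --tests levene,bartlett,fligner_killeen --out cohort0_stats.tsv
methvar adjust --stats cohort0_stats.tsv --mode z --seed 1 --out cohort0_adj.tsv
methvar meta --stats cohort0_adj.tsv --stats cohort1_adj.tsv --out meta.tsv
methvar regions --meta meta.tsv --annotation data/annotation.csv --out regions/
methvar enrich --meta meta.tsv --annotation data/annotation.csv \
    --sets sets.gmt --out enrich/
methvar covary --meta meta.tsv --catalog catalog.tsv --min-probes 10 \
    --out covariance.tsv
methvar all --config pipeline.yaml        # end-to-end, all strata
```

`pipeline.yaml` lists cohorts (beta/detp/intensity/samplesheet paths),
annotation, covariates, test selection, adjustment settings, strata
(`all`, `male_only`, `female_only`) and the global seed; see
`methvar.pipeline.DEFAULT_CONFIG` for all keys and defaults.

## Conventions

- Beta matrices: TSV, probes as rows, sample-ID header; `.gz` supported.
- Internal genomic coordinates are 1-based inclusive; BED export converts
  to 0-based half-open.
- Missing values are `NA`; all outputs carry `#` provenance headers
  (version, config hash, seed).
- Sign convention: positive Z = greater dispersion (or methylation) in
  cases.
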
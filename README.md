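# ctaging — cell-type-resolved transcriptomic aging analysis

`ctaging` is a Python toolkit for asking how aging reshapes gene expression
across the cell types of a tissue, built around single-nucleus RNA-seq
cohorts of postmortem human cortex (donors spanning decades of age, with and
without psychiatric diagnoses).  It implements the full analysis chain:

- **Pseudobulk differential expression.** Nucleus counts are summed per
  (cell type, donor), TMM-normalized, transformed to log₂-CPM with
  mean-variance precision weights, and fit gene-by-gene with a weighted
  linear model `expr ~ age + disease + sex + pH + RIN + PMI + lib_batch
  (+ PC1)`. The age coefficient is a log₂ fold change **per year**;
  Benjamini–Hochberg FDR for the age contrast is pooled across all
  (gene, cell type) tests.
- **Covariate selection.** Donor covariates are screened against principal
  components of the full-pseudobulk expression matrix; a hidden-confounder
  component (PC1 of the covariate-corrected matrix) can be appended to the
  design.
- **Aging-burden ranking by downsampling.** Equal-size nucleus subsamples
  (default 5,000 per cell type, 10 replicates) equalize statistical power
  before counting DE genes, so the ranking reflects biology rather than
  nucleus abundance; cell types are compared by two-sided Mann–Whitney
  U-tests (exact for small samples) with FDR correction.
- **Overlap statistics.** The symmetric overlap index
  `O(A,B) = (|A∩B|/|A| + |A∩B|/|B|)/2`, one-sided Fisher (hypergeometric)
  enrichment against a tested-gene background, Spearman correlation and
  direction concordance of shared effect sizes, and a 15th-percentile
  p-value rule for deciding which underpowered replication cell types are
  worth testing.
- **Rank–rank hypergeometric overlap (RRHO).** Stratified maps over rank
  thresholds of two signed rankings (metric: log₂FC × −log₁₀ p), signed
  positive for concordant and negative for discordant quadrants.
- **Transcriptomic age clock.** A weighted gene-panel score on the full
  pseudobulk, calibrated to years against chronological age; *age
  acceleration* is the residual after regressing out chronological age and
  library batch, tested for a disease-group offset with covariate
  adjustment.
- **Cell-composition trends.** Per-donor cell-type proportions regressed on
  age with covariate adjustment and FDR across cell types.
- **Synthetic cohort generator.** Every stage is testable without real data:
  a simulator plants known age slopes (majority downregulated), a
  high-burden cell type, a declining cell-type proportion, a clock panel
  with a disease acceleration offset, batch effects and negative-binomial
  noise, and reports the full ground truth.

## Worked example

```bash
python examples/02_differential_expression.py
```

prints (default simulated cohort, 40 donors × 8 cell types × 2,000 genes):

```
581 age-DE genes at FDR<0.05 across 8 cell types (46% downregulated with age)
among 629 planted age-regulated genes: 99.8% sign concordance, Spearman rho = 0.993
(estimates are log2 fold change per year of age; slopes near 0.03 mean a ~23% expression change over a decade)
```

i.e. the covariate-adjusted pseudobulk model recovers the planted aging
program almost perfectly: the direction of essentially every true
age-regulated gene is called correctly and the estimated per-year slopes
rank-correlate with the planted ones at ρ ≈ 0.99.  The other examples cover
simulation (`01`), burden ranking (`03`), overlap/RRHO (`04`) and the clock
plus composition trends (`05`).

The same analyses are scriptable from the shell:

```bash
ctaging simulate --out cohort/ --seed 1
ctaging de --cohort cohort/ --contrast age --out de_age.tsv
ctaging run --config examples/pipeline.yaml
```

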
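# Methods

This note documents the models, parameter choices and numerical conventions
behind `ctaging`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Pseudobulk differential expression

Nucleus-level counts are summed within each (cell type, donor) pair to a
genes × donors matrix, on the view that donors — not nuclei — are the
independent units for population inference.  Sample-level inference then
proceeds as in bulk RNA-seq:

1. **Filtering.** Nuclei with < 500 counts, < 300 detected genes or ≥ 15%
   mitochondrial reads are removed, then genes detected in < 500 nuclei.
   Per-cell-type assays drop donors contributing < 5 nuclei, drop the whole
   assay if fewer than 70% of donors remain, and keep genes with ≥ 10 counts
   in ≥ 80% of retained donors.  The 70% donor-retention fraction
   generalizes an absolute donor cutoff so the rule scales with cohort size.
   Stricter (90%) and looser (60%) gene-prevalence presets serve covariate
   selection and visualization/clock use respectively.
2. **Normalization.** Trimmed-mean-of-M-values factors: the reference donor
   has the upper-quartile of library-scaled counts closest to the cohort
   mean; M and A values over genes positive in donor and reference are
   trimmed (30% per tail on M, 5% on A) and the factor is 2 to the
   precision-weighted mean M, with factors rescaled to geometric mean 1.
   Expression is `log2((count + 0.5) / (libsize·factor + 1) · 1e6)`.
3. **Precision weights.** Per gene, the square root of the residual sd from
   an unweighted design fit is smoothed against average log₂ count (lowess,
   span 0.5); the trend value at each observation's fitted log₂ count,
   raised to the −4th power, is its weight.  Degenerate trends (no residual
   df, all-zero sds, < 10 genes) fall back to unit weights with a warning.
4. **Model.** Weighted least squares per gene on
   `age + disease_status + sex + pH + RIN + PMI + lib_batch (+ PC1)`, all as
   fixed effects.  Modeling batch/sex/disease as fixed rather than random
   effects targets the same age-slope estimand under reasonably balanced
   designs and keeps the fit closed-form; this is an intentional
   approximation to a mixed model.  Genes with < 2 residual df are reported
   untested.  A missing RIN is imputed with the cohort median.
5. **FDR scopes.** Benjamini–Hochberg; the age contrast is adjusted in one
   pool over all (gene, cell type) tests (default call threshold 0.05),
   while disease and age×disease contrasts are adjusted within each cell
   type (default 0.1).  The scope is carried in `DesignSpec` so it cannot be
   silently mixed.

## Covariate selection and the hidden-confounder PC1

The stringently filtered full pseudobulk is log-CPM transformed (replacing a
count-model variance-stabilizing transform — at pseudobulk depths both are
monotone stabilizers and the substitution drops a heavy dependency),
gene-centered, and decomposed by SVD.  Continuous covariates are tested by
Pearson correlation against each of the first 10 PCs, categorical ones by
one-way ANOVA of PC scores across levels (equivalent to canonical
correlation against a single categorical predictor, with a simpler
contract); covariates with any p < 0.05 are flagged.  The hidden-confounder
component is PC1 of the expression matrix after regressing out the selected
covariates per gene (residual + gene mean).  PC signs are fixed so each
component's largest-|loading| entry is positive, making outputs
deterministic.

**Caveat for synthetic cohorts:** the generator plants no hidden confounder,
so in simulated data this PC1 aligns with the strongest real signal — the
aging axis itself — and including it in the design absorbs the age contrast.
The recovery tests and the acceptance script therefore fit the measured
covariates without PC1; on real data, where PC1 captures unmeasured
technical structure, the full design applies.

## Burden ranking by downsampling

DE-gene counts scale with the number of nuclei behind each pseudobulk, so
raw counts rank power, not biology.  The procedure draws, for each of 10
replicates, 5,000 nuclei per cell type uniformly without replacement (seed
`seed XOR replicate`, so any replicate is independently reproducible),
rebuilds pseudobulk, reruns the age DE with the FDR pooled globally within
the replicate, and records the DE count per cell type.  Cell types with
fewer than 5,000 nuclei are excluded by default (an `allow_deficit` mode
keeps them with a non-comparable flag); sampling is unstratified by donor,
with a stratified option.  Pairwise two-sided Mann–Whitney U-tests compare
the replicate count vectors, BH-adjusted over all pairs.  The U statistic
uses midranks; p-values are exact (full enumeration of rank assignments,
`p = P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|)`, so identical samples give p = 1) up to
n₁+n₂ = 16 and otherwise use the tie-corrected normal approximation with
continuity correction, whose error against the exact tail is below ~0.03 at
n₁ = n₂ = 8.  With 10 replicates the smallest achievable exact two-sided p
for one pair is 2/C(20,10) ≈ 1.1 × 10⁻⁵; FDR granularity is limited
accordingly.

## Overlap machinery

The overlap index O(A,B) = (|A∩B|/|A| + |A∩B|/|B|)/2 gives both sets equal
weight regardless of size (0 by convention for an empty set).  Fisher
enrichment is the hypergeometric upper tail P(X ≥ |A∩B|) over a background
of tested genes; genes outside the background are dropped with a warning.
By default the background is the discovery signature's tested universe
(replication genes untested in discovery are removed), with an intersection
option.  The sample odds ratio reports ∞ when b·c = 0 with a·d > 0 — no
continuity correction is invented.  Effect concordance over shared genes:
Spearman ρ with midranks (exact permutation p for n ≤ 9, t-approximation
above) and the percentage of sign-equal effects, zeros counted discordant.
Underpowered replication cell types are screened by the rule "15th
percentile of nominal p-values < 0.1", with the percentile computed by
linear interpolation between order statistics.  Gene identity is by string
ID; cross-dataset symbol mapping is the caller's concern.

## RRHO maps

Each signature is collapsed to metric = estimate × (−log₁₀ p) (p floored at
1e-300), ordered descending with ties broken by gene id.  The map is a grid
over threshold pairs (multiples of `step = ceil(√N)` by default); at
(t₁, t₂) the overlap k of the two relevant sets is scored by the
hypergeometric upper tail with population N, set size t₁ and draws t₂,
computed in log space, and the cell holds the signed −log₁₀ p (capped at
300): positive in concordant quadrants, negative in discordant ones.  The
quadrant is set by each list's sign-split index (first rank with a negative
metric): top-t prefixes on the positive side, bottom-t suffixes on the
negative side.  Defining the "bottom t" set with size t (rather than
counting from the split) makes the (N, N) corner compare two full lists and
score exactly zero, and makes the map symmetric under transposition; the
price is that reversing one ranking flips cell signs only on the band of
thresholds where the quadrant class actually changes, which is what the
symmetry test asserts.

## Transcriptomic clock

The raw score is Σ w_g · expr(g, d) over a fixed externally trained panel
(weights ship as a TSV; panel genes missing from the matrix are dropped and
reported, never imputed) on log-CPM full-pseudobulk expression filtered at
the permissive 60% preset.  Calibration fits `raw ~ chronological age` by
OLS and inverts to years (the reverse regression is available as
`mode="predict"`; the acceleration test statistic is invariant to the affine
choice).  Age acceleration is the residual of calibrated age on
chronological age plus library-batch indicators; the group test regresses
these residuals on disease status with sex, pH, RIN, PMI and PC1 as
covariates, reporting the disease coefficient in years.

## Cell-composition trends

Proportions are nucleus counts per cell type over the donor's total.  Per
cell type, OLS of proportion on age plus sex, disease, pH, RIN, PMI and
batch; BH across cell types; significance at FDR < 0.05.  The per-type
linear model mirrors standard practice and ignores the simplex constraint —
slopes across cell types are not independent (a logit-response option exists
but is off by default).  A constant response is reported as slope exactly 0
with p = 1.

## Synthetic cohort generator

The generator emulates the statistical skeleton of a postmortem
single-nucleus aging cohort.  Defaults are desk-scale — 40 donors uniform on
26–84 years (40% disease cases), 8 cell types, 2,000 genes, ~600 nuclei per
donor at ~2,000 counts per nucleus — chosen so a full analysis runs in
seconds while preserving the moderate per-donor power of the real design;
paper-scale cohorts (~90 donors, ~20 cell types, thousands of nuclei per
donor) are one config away.  Structure:

- **Donors:** age, disease, sex, pH ~ N(6.5, 0.25), RIN ~ N(7.5, 1) (one
  value optionally missing, to exercise median imputation), PMI ~ N(30, 10)
  hours, and a library batch; both disease groups and batches are guaranteed
  non-empty.
- **Composition:** per-donor expected proportions drift on the logit scale
  (with a 1/(1−p) compensation so the realized marginal slope of a drifting
  cell type equals the configured proportions-per-year value, −0.002/yr for
  one cell type by default) and nuclei are allocated by a
  Dirichlet-multinomial (concentration 300) around them.
- **Expression:** gene relative abundances are lognormal with mild
  cell-type-specific offsets; per-nucleus depth is lognormal; counts are
  negative-binomial with dispersion 0.3 (variance μ + 0.3μ²).  Age effects
  are planted per (gene, cell type): a configurable fraction of genes (1%
  baseline, 10% in the designated burden cell type) receives |slope| ~
  U(0.005, 0.05) log₂/yr — straddling the strongest aging slopes observed in
  cortex — with exactly 60% negative; disease effects and batch effects are
  analogous log₂ shifts.  Down-flags are assigned, not sampled, so the
  planted down-fraction is exact whenever fraction × count is integral.
- **Clock:** a gene panel (default 50 genes, disjoint from the randomly
  flagged DE genes) carries coordinated slopes γ_g = 0.02·w_g log₂ per
  *effective* year, where effective age = age + 5·disease; the weighted
  panel score is then linear in effective age, planting a +5-year disease
  acceleration that the clock should recover.  Panel genes are genuinely
  age-regulated in every cell type and are recorded as such in the ground
  truth; fully null cohorts therefore also set the panel size to 0
  (`SimConfig.null()`).
- **Reproducibility:** one root seed feeds named `SeedSequence` substreams
  (donors, effects, composition, counts); fixed seed ⇒ bit-identical output,
  including written fixtures.

**What the synthetic tests do not show.** The generator has no ambient RNA,
doublets, nucleus-level mitochondrial biology (pct_mito is a bare metadata
scalar), no gene–gene correlation beyond the shared donor effects, no
nonlinear aging trajectories, and no hidden confounding.  Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimators under the stated generative model, not robustness to every
artifact of real tissue data.

## Problem sizes in tests and the acceptance script

Recovery and calibration experiments use: 20 null cohorts of 2,000 genes ×
8 cell types × 40 donors (~300 nuclei/donor) for false-discovery
calibration; one default planted cohort for sign/rank recovery; 10
independent 30-donor cohorts (1,000 genes, ~45,000 nuclei) for the
5,000-nucleus × 10-replicate burden ranking; 200 power and 500 null
simulations at the calibrated-age level for the clock test; 100 gene-label
shuffles for overlap specificity; and 100 null cohorts for composition
specificity.  These sizes were chosen to make binomial error bars on the
checked rates small while keeping the full suite desk-runnable.

## Known limitations

- Fixed-effect approximation to the mixed model (above); no empirical-Bayes
  variance moderation and no cross-cell-type effect shrinkage.
- The exact Mann–Whitney branch is O(C(n₁+n₂, n₁)) and is capped at
  n₁+n₂ = 16.
- TMM quantile-based trimming can differ from rank-based trimming by one
  gene at quantile boundaries.
- The RRHO down-quadrant convention is one of several in circulation; maps
  from tools using the suffix-from-position convention differ near the
  sign split.
- `compare_signatures` supports single-column contrasts only (no multi-level
  categorical contrasts).
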
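# Methods

## Statistical model

The pipeline targets cohorts with a gene × sample matrix of RNA-seq read
counts, a tissue label (normal/tumor) and right-censored overall survival
for the tumor samples. Survival is modelled on the accelerated failure
time (AFT) scale,

    log T_i = α + x_iᵀ β + σ ε_i,        ε_i ~ N(0, 1) i.i.d.,

with x_i a vector of standardized log-expression values. Under
right-censoring the least-squares criterion is weighted by Kaplan–Meier
jump (Stute) weights: with observations sorted by time (events before
censorings at ties),

    w_(i) = δ_(i)/(n−i+1) · Π_{j<i} ((n−j)/(n−j+1))^{δ_(j)},

the jump sizes of the Kaplan–Meier estimator of the time distribution.
Censored observations get weight zero; the weights sum to one exactly when
the largest observation is an event. Weighted least squares with these
weights is the classical consistent estimator for the AFT regression under
independent censoring, and every regression in the selection stage uses
them — including the standardization of predictors (weighted mean 0,
weighted variance 1), so censored samples cannot distort scales.

## Pipeline stages and defaults

**DE screen.** Per gene, a two-group negative-binomial Wald test:
median-of-ratios size factors; pooled method-of-moments dispersion
`α = (s² − m)/m²` floored at 1e-8; Wald statistic on the log2 ratio of
group means (pseudocount 0.5) with delta-method standard error;
Benjamini–Hochberg adjustment across genes. Thresholds follow common
practice for strong tumor/normal contrasts: `padj < 0.05` and
`|log2 FC| > 2`, both strict; the fold-change threshold is on magnitude,
so down-regulated genes qualify symmetrically. A low-count filter then
keeps genes with nonzero counts in at least `ceil(0.2 · n_samples)`
samples. The moment-based dispersion is deliberately simple — no shrinkage
across genes — which costs a little power at small n but keeps the test
fully self-contained; the null false-positive fraction is checked by
simulation in the test suite.

**Normalization.** log2 CPM with the 0.5/(lib+1) offsets; a lowess curve
(span 0.5, the reference default) of √(residual SD) against average log2
count; per-observation weights equal to the predicted √SD at the
observation's fitted log-count raised to the −4, clipped to the curve's
range. Residuals are taken around tissue-group means. When a gene subset
is transformed (e.g. after the DE screen), library sizes are taken from
the full count matrix, so CPM stays on the genome-wide scale — normalizing
against a few-hundred-gene "library" would couple every gene to the
dominant modules.

**Co-expression network.** Unsigned similarity |Pearson r| computed on
tumor samples only: tumor/normal mean shifts would otherwise induce strong
correlation between all differentially expressed genes regardless of
module, and the selection stage models tumor samples exclusively. The
soft power β is the smallest one whose scale-free fit index (signed R² of
the log–log degree-distribution regression over 10 equal-width bins,
floored at 0 for increasing laws) reaches 0.90. When no power reaches the
target the argmax is used; when the whole curve is uninformative (best fit
index < 0.3 — the generic outcome for block-structured data, whose degree
distribution is unimodal rather than scale-free) the conventional unsigned
default β = 6 is used instead, since an argmax over noise would typically
return β = 1 and erase edge contrast. Modules come from average-linkage
clustering of 1 − TOM with a static cut at the 0.90 quantile of the merge
heights; clusters under 30 genes join the noise module (label 0). The
static quantile cut is a deliberate simplification of dynamic tree cutting:
fully specified, parameter-light, and exact on block-structured data. Its
cut quantile trades fragmentation against merging — with a background of
unclustered genes the top merge heights belong to that background and 0.90
recovers planted modules essentially perfectly (ARI ≥ 0.99 in the test
conditions); quantiles ≥ 0.98 provably merge planted modules once the
number of between-module merges is below 2% of all merges. For dense
designs with no background a higher cut (e.g. 0.97) is appropriate; the
parameter is exposed everywhere.

**Two-step sparse boosting.** Componentwise L2 boosting of the
Stute-weighted, centred log survival time: at each of up to 500 iterations
the predictor minimising the weighted residual sum of squares under a
univariate weighted LS step is updated by ν = 0.1 times that step (exact
ties break to the lowest index). The reported model is the iterate
minimising

    BIC_m = n_eff · log(wRSS_m / n_eff) + df_m · log(n_eff),

with df_m the number of distinct predictors touched so far and n_eff the
number of positive-weight observations; iteration 0 (the null model) is a
candidate, so a module with no predictive genes yields an empty support.
Step one runs per module and condenses the selected genes into a super
marker (the fitted linear combination, one value per sample). Step two
boosts the same response on all active super markers jointly; modules with
nonzero joint coefficient are selected. Gene-level effect estimates are
the joint module coefficient propagated through the marker standardization
and the gene's step-one weight. Step-one gene weights are frozen in step
two — the super marker is meant to *represent* its module, not to be
refit. With full steps (ν = 1) on an orthonormal design the boosting path
reproduces OLS exactly, which the test suite uses as a closed-form oracle.

**Survival validation.** Per selected gene, patients split at the median
expression (strictly greater = "high"; ties fall to "low"), compared by
the standard two-group log-rank test (hypergeometric variance, χ² with
1 df). The sign of the accumulated observed-minus-expected events in the
high group gives the direction (`high_worse` / `low_worse`). No
multiplicity correction is applied across the selected genes, mirroring
common practice for post-selection KM displays; treat the p-values as
descriptive, not confirmatory.

## Synthetic cohorts

The generator emulates the statistical structure every downstream stage
assumes, not any particular dataset:

- **Counts**: negative binomial (gamma–Poisson, dispersion 0.1) around a
  log-normal baseline (median 100, log-SD 1). On the log2 scale each
  module gene adds `sd·(√ρ f_ms + √(1−ρ) e_gs)` with a per-module,
  per-sample factor f and unit latent SD, giving within-module log-scale
  correlation ρ (default 0.6). Background ("noise") genes have no shared
  factor.
- **Differential expression**: a fraction (default 0.8) of each module's
  genes shifts by ±de_log2fc (default 3) in tumor samples, with random
  direction. DE is confined to module genes: tumor-associated programmes
  are exactly what modules model, and keeping the unclustered background
  non-differential preserves the majority-unchanged assumption behind
  median-of-ratios normalization, as in a genome-scale experiment where
  most genes do not respond. Signal genes are always DE, so the screen
  cannot remove the survival signal by construction.
- **Survival**: log T = 6.5 + Σ β_j z_j + σε over tumor samples, with z
  the standardized log2 CPM of the signal genes (the same normalized scale
  the selection stage models), β = 0.5 for 5 signal genes in each of 3
  modules, and σ = 1 (residual spread of about one natural-log unit, a
  plausible residual heterogeneity for survival cohorts). Normal-tissue
  rows receive baseline-only survival so the clinical table has no missing
  fields.
- **Censoring**: independent exponential times whose rate is calibrated by
  bisection so the expected censored fraction matches `censor_rate`
  (default 0.3).

Defaults (300 tumor / 100 normal samples, 10 modules × 50 genes, 300
background genes) keep a full pipeline run under a second while leaving
each stage's inference non-trivial. Everything is reproducible from a
single integer seed; the pipeline fans the seed out to named per-stage
substreams via CRC-tagged `SeedSequence`s.

What the generator does **not** emulate: batch effects, tumor purity
gradients, GC/length biases, overlapping or hierarchically nested modules,
non-proportional or covariate-dependent censoring, and tied survival times
from coarse follow-up grids. Passing tests therefore demonstrate internal
consistency of the method under its own assumptions, not robustness to
these real-data phenomena.

## Numerical choices

- Weighted normal equations are solved exactly when the Gram matrix has
  condition number below 1e10; beyond that a ridge jitter of 1e-8
  stabilises near-singular designs (an exactly duplicated column splits
  its effect symmetrically), and a failure beyond the jitter raises an
  error naming the collinear columns. The conditional jitter keeps the
  uncensored fit equal to OLS at machine precision.
- Zero-variance predictors are excluded from boosting with a warning;
  zero-variance genes get zero similarity to everything in the network.
- A TOM matrix that is numerically all-ones (all genes identical) is a
  single module by definition; the clustering special-cases it.
- Genes with zero counts everywhere receive log2fc = 0 and padj = 1 in
  the DE test, and the minimum positive weight in the voom transform.
- The empirical-CDF tie rule (events before censorings) follows the
  standard Kaplan–Meier convention.

## Known limitations

- The selection stage's false-discovery proportion degrades when module
  genes are strongly correlated with the true signal genes: with ρ = 0.6
  a null module-mate's covariance with the response (≈ 1.5 in the default
  design) is close to a signal gene's (≈ 1.7), and correlated proxies
  enter the boosting path early. This is a property of the operating
  curve, not of the stopping rule: in the idealized uncensored design an
  oracle-stopped lasso shows a false-discovery proportion near 0.66 at
  sensitivity 0.8, and stricter (extended-BIC-style) penalties move along
  the same curve rather than above it. Module-level selection is much more
  reliable than gene-level selection and should be the primary read-out;
  genes within a selected module are best treated as a candidate set.
- Both selection steps reuse the same data, so super markers of truly null
  modules can carry in-sample overfit into the joint step; with many
  medium-sized modules expect occasional false module selections.
- BIC degrees of freedom count distinct touched predictors, which
  under-counts the effective complexity of shrunken fits.
- The static tree cut needs its quantile reconsidered when the expected
  number of modules or the background fraction changes drastically.
- The NB Wald test is anticonservative for very small groups (< ~10
  samples per arm); the suite checks calibration at n = 50 per arm.
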
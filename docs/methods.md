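# Methods

This note documents the statistical models, defaults and numerical choices
behind `reverseq`, and what the synthetic-data experiments do and do not
establish about behavior on real data.

## Differential expression (`reverseq.diffexpr`)

**Model.** Per gene, counts are negative binomial with mean
μ_gs = s_s · exp(β0 + β1 x_s) and variance μ + α μ², where s_s is a
per-sample size factor and x_s indicates the comparison group. β1 is the
natural-log fold change; log2FC = β1 / ln 2.

**Normalization.** Median-of-ratios size factors: for genes expressed in
all samples, the median across genes of count/geometric-mean, rescaled to
geometric mean 1. This is robust to a minority of differentially expressed
genes; it fails (by design, with an informative error) when no gene is
expressed everywhere.

**Dispersion.** Method-of-moments on normalized counts, pooled across
within-group residuals: α̂ = max(α_min, (s² − μ̄)/μ̄²) with α_min = 1e-8.
No shrinkage toward a mean–dispersion trend is applied — a deliberate
simplification relative to moderated estimators; with ≥ 8–10 samples per
group the unshrunk estimate is adequate, and at very small n the Wald test
compensates via its reference distribution (below). Genes with total count
< 10 in the contrast's samples are excluded before testing and before the
BH denominator (configurable), which stabilizes the moment estimate.

**Fitting.** The group log-means are exact NB MLEs obtained by damped
Newton iterations on the score equation Σ (y − μ)/(1 + αμ) = 0, vectorized
across genes (the score is strictly decreasing, so iterations are stable;
50 iterations, tolerance 1e-10). A group with all-zero counts gets the
pseudo-mean 0.5 on the normalized scale, which stabilizes the fold change.
SE(β1) comes from the expected Fisher information Σ μ/(1 + αμ) per group.

**Inference.** The Wald statistic β1/SE is referred to a t distribution
with n_A + n_B − 2 degrees of freedom rather than a standard normal. This
is a small-sample correction for the noise of the plug-in dispersion: with
a normal reference the null type-I rate at n = 10/group measures ≈ 0.066 at
the 0.05 level, while the t reference measures ≈ 0.049 with near-uniform
p-values (KS ≈ 0.01). The two references coincide as n grows. P-values are
BH-adjusted (step-up, missing values excluded from m); the default DEG
call is q < 0.05 with no fold-change cutoff.

**Known deviation from an idealized invariance.** Deterministically scaling
one sample's counts by c scales its size factor by c exactly, but does not
leave the result table bit-identical: the geometric-mean-1 rescaling shifts
all normalized counts, and the moment dispersion estimator treats the
scaled library as having lower relative variance (scaled counts are not a
realization of a deeper library). The fold-change perturbation is small
(99th percentile < 0.1 log2 units in testing) but not zero.

## The reversal coefficient (`reverseq.reversal`)

For a disease contrast (x = log2FC disease vs. control) and a treatment
contrast (y = log2FC treated vs. disease), the TLS slope is the closed-form
principal-axis slope b = (S_yy − S_xx + √((S_yy−S_xx)² + 4S_xy²))/(2S_xy);
degenerate S_xy = 0 cases: b = 0 when S_xx > S_yy, an error when the TLS
line is vertical (S_yy > S_xx), 0 by convention at equality. The intercept
is estimated, not forced through the origin (forcing a = 0 is available via
the paired table directly).

**Why TLS.** Both coordinates are estimates with comparable sampling error;
ordinary least squares of y on x would attenuate the slope toward zero. TLS
with isotropic errors is consistent for the structural slope, and adding an
isotropic cloud of null genes adds a multiple of the identity to the 2×2
scatter matrix, which leaves its eigenvectors — hence the slope — unchanged.
The residual anisotropy induced by the shared disease arm (the noise of x
and y is negatively correlated through the disease-arm mean) biases the
slope toward −1 by roughly v/S_xx, where v is the per-contrast fold-change
error variance; at the default study sizes this is < 0.01 and is covered by
the recovery experiments.

**Gene universe.** Default `union_significant` (q < 0.05 in at least one
contrast), matching the logic of color-coding significantly changed genes;
`all_tested`/`intersection_tested` fit on every shared gene. Both are
reported options because published reversal coefficients rarely state which
universe was used; the simulation experiments show the estimate is stable
across universes at realistic effect sizes.

**Uncertainty.** Percentile bootstrap over gene pairs (default B = 1000,
seeded). The interval is expanded, if necessary, to contain the point
estimate so the report invariant (CI ∋ estimate) holds even at tiny B.
Per-gene classes: reversed/concordant significant (both q < α, opposite/
same signs; a zero fold change has sign 0 and is never "reversed"),
disease-only, treatment-only, neither.

## Time-course signatures (`reverseq.signature`)

A gene is *consistently* regulated when q < α with the stated sign at every
timepoint. The Venn partition assigns each gene significant anywhere to the
exact subset of timepoints at which it is significant-in-direction; cells
are disjoint and their union is checked on every construction. A signature
is the intersection of the all-timepoints cell with a user-supplied
reference set (e.g. a 37-gene interferon-related DNA-damage signature
yields its hepatocyte-restricted subset); "sustained regulation" is
operationalized as q < 0.05 at every timepoint, since published derivations
state the outcome but rarely the thresholds. Reference sets are user input;
no curated lists ship with the package.

**Scoring.** Expression input is log2(normalized count + 1); signature
genes are z-scored and PC1 of the sample × gene matrix is the score. The
PCA sign is fixed so scores correlate non-negatively with the mean member
z-score, making cross-dataset comparisons deterministic. Fraction of
variance is λ1/Σλ. Correlation with phenotypes (Pearson default, Spearman
option) applies BH across the whole entity × phenotype table — matching a
single significance annotation over a correlation heatmap — rather than per
phenotype; pairs with < 3 complete observations are reported but excluded
from m.

## Preranked GSEA (`reverseq.enrichment`)

Ranking metric: sign(log2FC) · (−log10 p) by default (capped at ±308), with
log2FC available; ties break lexicographically by gene id so results are
deterministic. The enrichment score is the signed extremum of the weighted
KS running sum (hit weight |score|^p / Σ|score|^p with p = 1, miss step
1/(N − N_hits)); the running sum ends at zero by construction, which is
asserted in tests to 1e-9. The null is gene-label permutation (random
membership of the same size, shared across sets of equal size for
efficiency), the standard choice for preranked input where sample labels
are no longer available. NES divides ES by the mean |null ES| of matching
sign; nominal p is the fraction of sign-matched null ES at least as
extreme; FDR q compares the sign-matched pooled null and observed NES
distributions, capped at 1. With n_perm = 1000 the nominal p over random
sets is calibrated (type-I ≈ 0.047 with sd ≈ 0.015 over 200 sets — the
binomial floor of that measurement size). A one-sided hypergeometric
over-representation helper with BH covers Venn-cell annotation.

## Deconvolution (`reverseq.deconv`)

Bulk profiles are modeled as non-negative combinations of cell-type
reference profiles and solved per sample by active-set NNLS; weights are
renormalized to proportions (all-zero profiles or degenerate fits fall back
to uniform with a warning). Both sides are CPM-normalized in linear space
before fitting, so "proportions" are fractions of library-normalized RNA
content — the identifiable quantity; converting to cell-number fractions
would require per-cell RNA content, which is out of scope. This is a
transparent, dependency-light formulation of the signature-based
deconvolution family; support-vector variants are out of scope. Group
differences per cell type use one-way ANOVA plus Tukey HSD.

## Mendelian randomization (`reverseq.mendelian`)

Two-sample MR from instrument-level summary statistics (eQTL effect on an
expression exposure; GWAS effect on an outcome trait). Wald ratio
β_out/β_exp with first-order SE se_out/|β_exp| by default; the delta-method
SE adding the exposure-noise term is available. The fixed-effect IVW
estimate is the inverse-variance-weighted mean of ratios, SE = (Σw)^{-1/2},
Cochran's Q against χ²(J−1) for heterogeneity, and an optional
multiplicative random-effects SE inflation √(max(1, Q/(J−1))). Instrument
selection (clumping, eQTL p-thresholds) is upstream: the module consumes an
already-selected table and refuses β_exp = 0 instruments. Scans over
exposure–outcome pairs apply BH across pairs, with failed pairs recorded
and excluded from m. Pleiotropy-robust estimators (Egger, weighted median)
are out of scope.

## Synthetic data (`reverseq.synth`)

What the generators emulate, and the defaults:

| Generator | Emulates | Key defaults |
|---|---|---|
| `gen_counts` | three-arm (control/disease/treated) liver RNA-seq | 10,000 genes, 10/arm; baseline lognormal(ln 200, 1); dispersion lognormal(ln 0.08, 0.3); π_disease = 0.2; δ ~ N(0, τ²), τ = 2 log2 units; reversal fraction ρ = 0.5 |
| `gen_timecourse` | vehicle vs. drug in cultured hepatocytes at 6/12/24 h | 2,000 genes, 4/group/timepoint; effect 1 log2 unit; persistence classes all/late/early/null at 10/10/10/70%; dispersion lognormal(ln 0.01, 0.3) |
| `gen_phenotypes` | strain phenotypes linearly coupled to a signature score | user-specified betas and noise |
| `gen_mr_summary` | eQTL/GWAS instrument tables with known θ | J instruments, β_exp ~ N(0, 0.3²) truncated at 2·se_exp (weak instruments excluded) |
| `gen_mixture` | bulk profiles as convex mixtures of cell-type references | noise optional; proportions on the simplex |

Dispersion defaults differ by design: tissue-level studies (three-arm) use
0.08, typical of between-animal biological variability, while the time
course uses 0.01, typical of isogenic culture replicates. Library-size
factors are log-uniform in [0.5, 2] so normalization is exercised
non-trivially. All generators are bit-reproducible from their seed.

**What passing tests do not show.** The simulations draw genes
independently (no co-expression beyond the planted signature factor), use
a single dispersion trend-free model, include no batch effects, outliers,
GC/length biases, or annotation error, and couple phenotypes linearly with
Gaussian noise. Recovery and calibration results therefore validate the
estimators under their assumed models, not robustness to the full
messiness of real cohorts; on real data the reversal coefficient should be
read alongside its bootstrap CI and the per-gene classification.

## Problem sizes and numerical notes

The recovery experiments use 10,000 genes × 10 samples/arm × 20 seeds per
reversal fraction (the DE fits are vectorized across genes, so a full
three-arm analysis takes well under a second); GSEA calibration uses 1,000
permutations over 200 random sets on a 1,000-gene ranking; MR calibration
uses 200 recovery and 1,000 null replicates at J = 50. Tolerances: TLS
closed form vs. orthogonal-distance search 1e-6 (the search grid/refinement
limits agreement, not the closed form); ES vs. naive running sum 1e-12;
noiseless NNLS recovery 1e-6 L1. Ties in rankings and sort-order-dependent
steps use stable sorts with lexicographic tiebreaks; every stochastic stage
takes an explicit seed and records it in its output header.
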
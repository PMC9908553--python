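# Methods

`ensembletx` implements an ensemble diagnostic-classification pipeline for
case-control transcriptomic cohorts, together with the synthetic cohort
generator used to exercise it and the downstream statistics it reports. This
note documents the models, the defaults and why they were chosen, and the
numerical decisions made where the design was genuinely open.

## The classification platform

A *model* is a four-step chain applied to a preprocessed gene × sample
log-expression matrix:

1. **Filtration** (5 methods): unsupervised culling by dispersion — none,
   drop the 50% of genes with smaller coefficient of variation (`cov`),
   smaller variance (`var`), both in sequence retaining 25% (`cov_var`), or
   keep the top 25% by variance (`varImportance`).
2. **Selection** (102 methods in seven families): supervised choice of a gene
   subset — none; absolute standardized group difference (`zscore`, with
   Welch-t, signal-to-noise, and median/MAD variants); moderated- or
   ordinary-t ranking (`de`); univariate score-and-threshold (`select`, with
   F-statistic, mutual-information and rank-sum scores); recursive feature
   elimination under a linear maximum-margin classifier (`svm`, three
   regularization levels); running-sum gene-set enrichment against the
   group-difference ranking (`gsea`, three synthetic set collections); and
   hub-gene ranking on a co-expression relevance network (`grn`, Pearson,
   Spearman or binned-mutual-information association, top 1% of edge
   strengths, degree ranking). Subset-size families run over
   k ∈ {10, 25, 50, 100, 250, 500}.
3. **Reduction** (7 methods): none; correlation-clustering eigengenes
   (average-linkage on 1 − |r|, tree cut at height 0.75, one sign-anchored
   first principal component per module); forward stepwise logistic selection
   with BIC stopping; sure-independence screening keeping ⌊n/log n⌋ genes by
   marginal correlation; principal-component regression; partial least
   squares; and powered PLS (loading weights ∝ sign(r)·|r|^γ·sd^(1−γ),
   γ = 0.5, with standard PLS deflation). Latent-component methods emit 5
   component scores by default, clamped to what the data supports.
4. **Classification** (12 adapters): linear regression on the 0/1 label,
   logistic regression, LDA, QDA, ridge and lasso regression, ridge/lasso/
   elastic-net logistic regression, gradient boosting with the Bernoulli
   deviance, random forest, and bagged trees. Every adapter returns one
   finite score per sample, higher = more case-like; ranking metrics need no
   thresholding. Hyperparameter grids are small fixed defaults; grids with
   more than one point are resolved by AUC-ROC on an inner stratified 75/25
   split of the training fold.

The default registry crosses to 5 × 102 × 7 × 12 = 42,840 model
specifications (3,570 feature routes). The exact composition of the
102-method selection axis is a registry design choice: the seven families
are fixed, and the per-family parameter grids were chosen to be useful and
to sum to the platform's structural count (the moderated-t family carries
one extra small-k setting relative to the ordinary-t family to close the
sum; shrinkage matters most at small k).

### Sweep and gating

Model evaluation uses 5 seeded stratified random 80/20 holdout iterations:
route and classifier are fitted on the 80%, AUC-ROC and average precision
are computed on the held-out 20%, and the 5 values are averaged. This is the
repeated-holdout reading of "five-fold" evaluation; a classic stratified
5-fold switch is available (`SweepConfig(classic_kfold=True)`). Stratified
splits prevent single-class folds in small cohorts. Routes that cannot
produce a qualified, non-constant feature set on some fold (and classifiers
that cannot fit, e.g. QDA with more features than per-class samples) mark
the spec infeasible; infeasibility is recorded, never fatal.

Specs whose mean training-CV AUC-ROC reaches 0.80 are refit on the full
training set (standard practice; the refit uses all training information)
and scored exactly once on the held-out test cohort; those that also reach
0.80 there form the ensemble pool. Train/test sample-id overlap is a hard
error.

### Bayesian model averaging

Member weights are w_i = (AUC_i − 0.7) / Σ_j (AUC_j − 0.7) with AUC_i the
training-CV AUC-ROC; the 0.8 gate guarantees positive weights. The prose
description of a squared weight is exposed as an option
(`squared_weights=True`) but the displayed linear form is the default.
Member outputs are heterogeneous (probabilities, margins, raw regression
predictions), so each member's score is min–max mapped to [0, 1] using that
member's own full-training-set scores before weighting; without this the
weighted sum would mix incommensurate scales. The weighted sum is rescaled
to [0, 1] by min–max bounds fixed on the training cohort; held-out samples
outside those bounds clamp. Rescaling by the scored batch's own range is
available (`use_training_bounds=False`) but training-bounds rescaling is the
default because it keeps test scores comparable to training scores.
ASD-group stratification splits at the case-group mean of the rescaled
scores, with scores exactly at the mean counted as "above".

### Permutation null

The null experiment shuffles the diagnosis labels of the training cohort,
re-runs the full sweep with an 85/15 train/validation split, and pools every
feasible model's mean AUC-ROC. Because all models within one replicate share
the same permuted labels and the same five splits, their scores are strongly
correlated and the pooled median from a single permutation is itself noisy;
the reported null statistics therefore pool several independent permutation
replicates (4 in the full-scale run, more in the desk-scale calibration
test). Even pooled, the null median carries a stochastic spread of a few
hundredths of an AUC unit; its expected value is 0.5.

## Preprocessing

Probe-level intensities with detection p-values pass a two-step expression
filter: (1) detected (p < 0.05) in at least 3 samples; (2) intensity above
the 95th percentile of the pooled negative-probe intensities (probes with
p > 0.1 in every sample) in at least 50% of samples. The percentile uses
linear interpolation between order statistics (the convention is
configurable; nothing in the procedure pins it down). Quantile normalization
forces every sample onto the mean distribution of order statistics, with
within-column ties receiving the mean of the reference values at the tied
ranks. Multi-probe genes collapse to the probe with the highest mean across
samples (ties break to the lexicographically smaller probe id). A log2
transform follows collapse — standard for array intensities and required for
log-fold-change semantics — with detection thresholds applied to raw
intensities. Re-applying the filter to already-filtered data requires the
recorded background threshold, since the negative-probe pool is gone.

## Synthetic cohorts

The generator emulates a 240-subject (175 train / 65 test; 127 case /
113 control) leukocyte array cohort. Per gene g, log2 expression is
base_g + δ_g·d_s·σ_g + N(0, σ_g²): σ_g² is scaled inverse-chi-squared
(d0 = 4, s0² = 0.09) so that empirical-Bayes shrinkage downstream operates
under its own model assumption; δ_g ∈ {−1, +1} for the truth-DE subset
(default 10% of genes) and 0 otherwise; d_s is 1.2 σ for full-effect cases,
0.4 σ for the attenuated case subgroup (45/124 of cases — the generator's
stand-in for the below-the-ensemble-mean stratum), and 0 for controls. Genes
expand to 2 probes each (offset sd 0.3, noise sd 0.1), plus 5% junk probes
at background intensity that are never detected, providing the
negative-probe pool. Detection p-values are < 0.04 in 95% of sample-probe
pairs for expressed probes. Mutation-carrier flags are drawn independently
of expression at 13/112 (cases) and 12/105 (controls); severe prenatal-event
flags at 19/79 (full-effect), 20/45 (attenuated) and 24/107 (controls), with
matching control-event rates; ages are per-group lognormal (cases
50.8 ± 28.8 months, controls 34.5 ± 8.4), reproducing the cases-older
confound that the post-hoc age-bin tests probe. All randomness flows from
one seed through split substreams, so the phenotype draw is invariant to the
gene count.

What the generator does **not** emulate: batch effects, bead-level noise,
sex (single-sex cohort), realistic gene-gene correlation (independent genes
by default; an equicorrelated block option exists but is off), or any
coupling between carrier status and expression. Passing tests therefore
demonstrate the pipeline's statistical machinery — calibration under the
null, signal recovery under the stated effect-size model, leakage freedom —
not performance on real cohorts.

## Downstream statistics

- **Moderated t**: gene-wise residual variances s_g² (d_g df) shrink toward
  a prior (d0, s0²) estimated by closed-form moment matching of log s_g²
  (trigamma inversion by Newton iteration); posterior variance
  (d0·s0² + d_g·s_g²)/(d0 + d_g), t on d0 + d_g df capped at the pooled
  residual df; when the observed variances are under-dispersed the prior df
  is infinite and s0² is the arithmetic mean of the s_g². This is the
  standard (non-robust) empirical-Bayes variant; the robust variant is out
  of scope. Significance flags require Benjamini-Hochberg adjusted p < 0.01
  and |logFC| > 0.1. Zero-variance genes yield guarded infinite t with p = 0
  and a log entry.
- **Fisher exact / odds ratio**: two-sided exact p (sum of
  fixed-margin tables no more probable than observed); the odds ratio is the
  conditional MLE — the ψ solving E_ψ[a | margins] = a on the Fisher
  noncentral hypergeometric distribution, found by bracketed root-finding on
  log ψ to 1e-12 — matching what exact-test software reports. A zero margin
  yields p = 1 and an undefined (NaN) odds ratio. Contingency rows are
  ordered (focal group, reference group).
- **Mutation presence/absence classifier**: carriers called cases;
  tp/fn/fp/tn from the carrier counts, accuracy/precision/recall as exact
  ratios (precision NaN-signaled when no subject carries a mutation).
- **Welch t** with Satterthwaite df; **one-way ANOVA** (classical
  decomposition); **Games-Howell** pairwise comparisons (Welch-type SE and
  df, q = |Δ|·√2/SE against the studentized-range distribution with k
  groups — family-adjusted by construction; with two groups this reduces
  exactly to the Welch t test).
- **Age bins**: fixed at [0, 20), [20, 31), [31, 49] months; ages above 49
  are flagged ">49" rather than dropped; negative ages are errors.
- **Score regression**: OLS of the ensemble score on the group indicator,
  centered age, and their product, with a rank check that names the
  redundant column on collinear designs.

## Problem sizes and tolerances

Desk-scale runs use 2,000 genes (the nominal expressed-transcriptome scale
is ~14,000; the generator accepts it, and sweeps subset the registry
accordingly). The reduced registry used for permutation experiments is
2 filtrations × 10 selections (all seven families, cheaper grid points) ×
5 reductions × 12 classifiers = 1,200 models. The acceptance script pools
4 permutation replicates of that sweep. Root-finding tolerances: 1e-12 on
the CMLE log-odds; 1e-10 relative on trigamma inversion. Tie-breaks are
deterministic everywhere (stable sorts; lexicographic probe ids), and every
stochastic component takes an explicit seed.

## Known limitations

- The per-method fidelity of the 102 selection methods to any particular
  published platform is not verifiable; the family architecture and counts
  are what the registry preserves.
- The `grn` family is interpretive: degree ranking on a relevance network is
  one reasonable operationalization of network-based selection.
- The eigengene reduction clusters on plain correlation distance, not
  soft-thresholded topological overlap; eigengene extraction is the part the
  pipeline consumes.
- Regression-type classifiers feed raw predictions to the ranking metrics;
  no probability calibration is attempted.
- The ensemble's absolute performance numbers on synthetic cohorts depend on
  the generator's effect-size model and are not comparable to any real
  cohort's.
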
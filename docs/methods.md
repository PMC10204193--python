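# Methods

## Signature construction and refinement

The generic G0-arrest signature is derived from differential-expression
tables contrasting cycling cells with cells in five forms of quiescence
(spontaneous, contact inhibition, serum starvation, CDK4/6 inhibition, MEK
inhibition). `refine_signature` applies, in order: (0) adjusted p < 0.05 in
all five forms; (1) identical fold-change sign in all five forms (genes
with a zero fold change in any form fail); (2) removal of genes on an
explicit exclusion list (other cell-cycle stages); (3) against a reference
cohort, removal of genes whose across-sample SD *or* mean expression falls
below the 10th cohort percentile, or whose absolute Pearson correlation
with the mean expression of the DREAM-complex target set is below 0.3.
Filters (1)–(3) are set intersections given fixed thresholds, so
re-applying the pipeline to its own output is a no-op. The numeric
thresholds of filter (3) are package defaults — the underlying selection
idea fixes only "low variability, low expression, low DREAM correlation" —
and all are configurable. The DREAM filter is computed against the target
set's *mean expression* rather than a derived DREAM activity score; with
strongly co-expressed targets the two are nearly collinear and the mean is
the simpler estimand.

Stress-programme signatures (`build_stress_signatures`) take, per form,
genes significant for that form only, apply the structural filters, rank
by |log2 fold change| and keep the top 10 per direction; ties at the
boundary break alphabetically so results are reproducible across runs.
Fewer than 10 survivors in either direction is an error naming the form
and direction rather than a silently smaller signature.

The vendored signature files carry synthetic placeholder identifiers (the
published gene lists live in supplementary material not redistributed
here); set sizes (139, 35, 50) and the subset relation between the minimal
and generic signatures are preserved, which is what the toolkit's logic
and tests depend on.

## Scoring

`combined_zscore` standardises each gene across the cohort with the n−1
SD, sums z-values per direction divided by √n of the genes actually used,
and subtracts the down-score from the up-score. Zero-variance genes
contribute 0 and are excluded from the √n normaliser; signature genes
missing from the matrix (dropout) are excluded and counted in
`n_up_used`/`n_down_used`. The score is invariant under any gene-wise
positive affine transform of the input, so it is insensitive to per-gene
scaling and offset differences between platforms. Because standardisation
is cohort-relative, the score is a *within-cohort* contrast: a cohort
consisting entirely of arrested cells scores near zero everywhere. This
matters when interpreting single-condition datasets.

The mean-scaled score `G0m = (mean G_U − mean G_D)/mean G_H` operates on
linear-scale expression and is invariant under global rescaling;
housekeeping genes overlapping the signature are excluded from G_H at
scoring time. The rank score (mean normalised mid-rank of up genes minus
down genes, ranks mapped to [0, 1]) is a deliberately simple rank-based
comparator, not a reimplementation of published rank-scoring methods.

Purity adjustment divides linear-scale expression by the per-sample tumour
purity (log2 values have log2(purity) subtracted — the `log_scale` flag
governs which path runs) and removes samples below 30% purity. Division is
one reading of "scaled according to purity"; a `none` mode applies only the
cutoff for users who prefer their own adjustment.

State calling uses a strict `score > threshold` rule with threshold 0 by
default. Cohort-level high/low partitioning (`kmeans_high_low`) removes
batch/tissue structure first, then runs k-means (k = 2, 25 restarts,
seeded) on the signature-gene submatrix and orients the labels by mean
combined Z-score. ROC AUC uses the rank (Mann–Whitney) formulation with
mid-rank tie correction, verified in tests against an explicit
threshold-sweep trapezoidal oracle.

## Batch adjustment

Batch effects are removed by per-batch gene-wise location–scale
standardisation — each gene is centred and variance-scaled within every
batch, then (optionally) mapped back onto the gene's pooled mean/SD. This
is a deterministic, shrinkage-free counterpart of empirical-Bayes methods
such as ComBat: adequate for location/scale batch structure and for the
planted-effect settings the tests exercise, but it will over-correct
genes whose biological signal is confounded with batch, and it performs no
shrinkage for small batches (batches of one sample are rejected). For
kNN classification the pooled rescaling is skipped so the adjusted space
is exactly invariant to batch-wide gene-wise affine transforms of the
query; for k-means partitioning the rescaled form keeps values on the
expression scale.

## Stress-response subtyping

Bulk rule: a sample must first show a positive generic G0 score; the
top-scoring programme is accepted only if its score exceeds the cohort
mean by one SD of that programme's score distribution *and* a two-sided
Welch t test finds its per-gene signed z contributions higher than the
pooled contributions of the other four programmes (α = 0.05); otherwise
the sample is `uncertain`. A per-sample t test between programme *scores*
is not defined (one number per programme); the per-gene contributions are
the only within-sample replicates, so the test runs over those. Welch's
form is used because the candidate (20 genes) and pooled (80 genes)
contribution sets have no reason to share a variance.

Single-cell rule: restrict to shared genes, batch-adjust query vs
reference, fit PCA on the *combined* matrix (10 components by default,
centred but not re-scaled — genes are already standardised by the
adjustment), then classify each query point by its 3 nearest reference
profiles with 2 identical votes required; distance ties at the k-th
neighbour break by reference sample ID. PCA on the combined data (rather
than reference-only) keeps query and reference in a common basis at the
cost of letting query composition influence the axes; with balanced
references the difference is negligible.

## Genomic dependency modelling

The mutation-rate covariate is log10(n_mutations / 38 Mb), the exome
capture length; zero counts require an explicit pseudo-count floor. Driver
prioritisation runs a 2×2 Fisher's exact test per binary event against
high/low arrest groups with Benjamini–Hochberg correction at q < 0.05 —
the simplest exact test matching an enrichment/depletion question on
event indicators.

`ensemble_elastic_net` drops samples with fewer than 50 mutations, then
refits an elastic net on random 90% subsamples (without replacement);
features with nonzero coefficients (|coef| > 1e-8) in every iteration form
the consensus, and their coefficients are averaged across iterations.
Hyperparameters are tuned by 10-fold cross-validation over an l1-ratio
grid (0.1…1.0) and an automatic penalty path. Two deliberate choices:

* **Penalty rule.** The default picks the strongest penalty within one
  standard error of the CV minimum (the glmnet `lambda.1se` convention)
  rather than the CV minimum itself. Minimum-CV penalties optimise
  prediction and persistently retain small spurious coefficients that the
  all-iterations intersection cannot remove (90% subsamples are too
  correlated); the 1-SE rule targets support recovery, which is what the
  consensus set is for. `alpha_rule="min"` restores the prediction-optimal
  behaviour.
* **Tune once.** Hyperparameters are tuned once on the full filtered
  training set and reused across iterations; re-tuning inside every 90%
  subsample (`tune_per_iteration=True`) multiplies runtime by the CV cost
  for nearly identical selections.

Continuous covariates are standardised, binary event indicators stay 0/1,
and categorical tissue labels are one-hot encoded. The consensus linear
model uses the averaged coefficients with intercept
`mean(y) − Σ coef·mean(x)` so it is unbiased at the training means, and
stores those means. Shapley attributions are exact for linear models under
the independent-features convention: φ_jk = coef_k·(x_jk − mean_k),
additive to `prediction − prediction-at-means`; tests verify equality with
exhaustive-permutation Shapley on small instances.

The tissue-level classifier ranks features by one-way ANOVA F statistic,
keeps the top 30, and averages random-forest accuracy (500 trees, seeded)
over 5 stratified 80/20 splits.

## Signature reduction

Per training dataset, seeded random forests predicting the cell state from
the signature genes are trained repeatedly; per-gene Gini importances are
averaged over repetitions and then min–max normalised per dataset
(averaged-then-normalised; normalising each repetition first would weight
noisy repetitions equally). Candidate subsets take every gene above a
threshold in at least one dataset, sweeping thresholds 0…1 in steps of
0.01 with duplicate subsets collapsed to their smallest threshold. Each
candidate is scored on an external validation cohort with the combined
Z-score and correlated with the experimental arrest measurements;
candidates whose mean assay correlation is significant (p < 0.05 via the
t transform) qualify, the winner maximises the designated primary assay's
correlation, and ties go to the smaller subset. The shortlist rule before
the primary-assay tiebreak is intentionally simple (significance gate on
the mean correlation); no sharper rule is specified by the selection
problem itself.

Defaults: 1000 repetitions of 500-tree forests reproduce the reference
procedure; the test suite and CLI default to 100 repetitions of 50–500
trees, which give indistinguishable rankings on the planted-effect
simulations at a fraction of the cost.

## Synthetic data

The generators plant known truth into every structure the methods assume:
two-state populations with signature genes shifted ±δ in arrested
cells/samples; Bernoulli dropout applied post hoc to single-cell values;
per-batch additive offsets; purity mixing as a linear-scale convex
combination with a fixed normal-tissue profile (the unshifted gene
baseline) at weight 1 − purity; five stress programmes with
programme-specific shifts plus a shared generic-arrest shift and labelled
reference profiles; and binary genomic features with planted linear
effects and mutation counts straddling the 50-mutation filter. Default
conditions are 200 cells/samples, 50% arrested, effect size 3 log2 units,
20% dropout, purity uniform on [0.3, 1]; these are the conditions used by
the test suite throughout.

One global seed fans out to per-component streams via `SeedSequence`
spawning, so every generator is a pure function of (config, seed) and
sub-simulations are independently reproducible.

What the generators do *not* emulate: count-based noise (negative binomial
mean–variance coupling, library-size variation), expression-dependent
dropout, correlated gene modules beyond the planted signature, and
realistic mutation co-occurrence. Passing tests therefore demonstrate
correctness of the algorithms under their own assumptions — monotone
planted effects with Gaussian noise — not performance on real tumour
data, where effect sizes are smaller and confounding is richer.

## Problem sizes and numerics

The test suite runs at desk scale: cohorts of 60–500 samples, gene
universes of 100–1000, 20-seed replications for stochastic claims, 100
ensemble iterations and 100 forest repetitions. Floating-point guarantees
asserted by tests: scoring primitives match brute-force oracles to 1e-9;
Shapley additivity holds to 1e-10; seeded runs are bit-reproducible.
Degenerate inputs (single-sample cohorts, zero-variance genes, empty gene
overlaps, single-class labels, zero mutation counts, empty consensus
sets) raise typed validation errors or documented warnings rather than
propagating NaNs.

## Known limitations

* Cohort-relative scoring cannot produce absolute arrest fractions; the
  default call threshold of 0 is permissive and should be calibrated per
  cohort (survival-optimal cutoffs are cohort-specific and deliberately
  not baked in).
* The location–scale batch adjustment is not ComBat: no empirical-Bayes
  shrinkage, no covariate preservation.
* The bulk subtype t test over per-gene contributions is one
  interpretation of a per-sample significance requirement; programmes
  with overlapping gene sets weaken its assumptions.
* The vendored signatures are placeholders for structure and testing, not
  biological gene lists.
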
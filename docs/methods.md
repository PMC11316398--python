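# Methods

## Overview

`pathstack` implements a biologically informed, two-stage ("stacked")
classifier for case–control omics data, together with the downstream
interpretation machinery that makes the intermediate representation
useful: feature ranking and pathway-module discovery.

The motivating problem: a typical methylation or expression study has
10⁴–10⁵ features and at most a few hundred samples. Fitting one model on
all features ignores the strong prior that features acting through the
same biological process are exchangeable evidence for that process.
`pathstack` therefore stratifies the features by pathway membership,
learns one *pathway-level* meta-feature per pathway, and fits the final
model on the (much smaller) pathway-feature matrix.

## Stage 1 — pathway compression

For pathway *k* with feature block `X_k` (M samples × n_k features) and
binary labels `y` (0 control, 1 case):

1. Repeat B times: draw a seeded stratified `n_folds`-fold partition of
   the samples.
2. Within each training fold, keep features with |PCC(feature, y)| above
   `cutoff` (grid {0, 0.05, 0.1, 0.2, 0.3, 0.5}); if none qualify, keep
   the `fallback_k` = 10 features with largest |PCC|.
3. Fit the stage-1 learner on the surviving features, and record the
   class-1 probability for each held-out sample.
4. The pathway score `Ŷ⁽¹⁾_k` is each sample's out-of-fold probability
   averaged over the B repetitions.

Feature screening runs strictly *inside* each training fold, so a
sample's own label never influences its score. A `resampling="bootstrap"`
switch replaces the fold partition by bootstrap resampling with
out-of-bag scoring (averaging over the repetitions in which a sample was
out-of-bag); cross-validation is the default because it scores every
sample in every repetition, which the downstream matrix contract
requires.

Fold partitions and learner seeds derive from
`(global seed, pathway index, repetition index)`, making pathways
independent of execution order: one worker or many give bitwise-identical
matrices.

Scoring new samples uses a separate state: per pathway, the feature
subset selected on the full training set and a learner refit on the full
training set. (Averaging the fold models would be an alternative; the
refit gives a simpler, single-model contract per pathway.)

## Stage 2 — assembly and final model

The stage-2 design concatenates:

* pathway columns that pass (a) a strict positivity filter
  (PCC(column, y) > 0 — under pure noise, out-of-fold scores inversely
  associated with the outcome arise by chance and carry no reusable
  signal; constant columns, whose correlation is undefined, are dropped)
  and (b) greedy de-correlation: columns are visited in descending
  outcome-PCC order and kept only if their |PCC| with every already-kept
  column is ≤ `stage2_cutoff` (grid {0.8, 1.0}; 1.0 disables pruning).
  The positivity filter runs first so the greedy order is well defined on
  the surviving set; on duplicate-free positive designs the two filters
  commute (property-tested).
* the `top_n` unmapped features by |PCC| with the outcome, appended raw.
  "Unmapped" defaults to all features not represented by a retained
  pathway (strictly unannotated plus annotated-but-unretained); a
  `strict` mode restricts to features with no gene annotation at all.
  The positivity rule does not apply here — it is scoped to
  pathway-level scores.

`top_n` is treated as a hyperparameter of the framework: with
`top_n=None` (default) the value is chosen from the grid
{0, 100, 300, 500, 1000} by stratified 5-fold CV AUC on the training
data, re-running the unmapped ranking and both pathway filters inside
each fold; ties prefer the smaller value. A fixed integer bypasses the
selection.

If every column is filtered away (possible with a constant or
anti-correlated score matrix), the pipeline falls back to predicting the
training class prior rather than failing.

## Evaluation

Metrics: AUC (Mann–Whitney pair statistic), PRAUC (area under the
precision–recall step curve, ties grouped per threshold), balanced
accuracy at a fixed probability threshold of 0.5 (configurable; the
threshold choice is a documented convention, not part of the method),
and the Pearson correlation between predicted probabilities and the 0/1
labels. An undefined correlation (constant predictions) is recorded as
missing and excluded from the mean, with the count reported.

The evaluation harness is *nested*: the outer loop is r repetitions of
stratified k-fold CV (10 × 5 by convention), and for each outer fold the
entire pipeline — stage-1 out-of-fold matrix, positivity/pruning,
unmapped selection, stage-2 fit — is re-run on the outer-training
samples only. Reusing in-sample stage-1 scores across the outer boundary
would leak labels into the test fold; the harness never does. Summary
tables report the mean, the SD over all r·k folds and the SD over the r
repetition means (publications are often silent about which of the two
they print, so both are kept).

The conventional baseline ranks all features by |PCC| inside each
training fold, keeps the top N (grid {500, 1000, 2000, 5000, 10000,
15000}, clamped to the feature count with a warning), fits one learner,
and reports the N with the best mean AUC.

Base learners (both stages and baseline): decision tree, RBF-SVM
(decision values mapped through a sigmoid link — downstream use needs
monotone [0,1] scores, not calibrated probabilities), random forest,
Gaussian naive Bayes, logistic regression, L2-regularised logistic
regression, k-NN, gradient boosting, Gaussian process, elastic-net
logistic regression, plus a training-prior dummy used as a negative
control. No hyper-parameter optimisation is performed on the base
learners; all run at fixed conventional settings.

## Ranking

Pathway score columns and raw input features are ranked by a univariate
logistic *score* test (statistic U²/V with U = Σ xᵢ(yᵢ − ȳ) and
V = ȳ(1−ȳ)Σ(xᵢ−x̄)², χ²₁ under the null). The score test is preferred to
the Wald test because it stays defined under complete separation, and it
is applied identically at both levels for internal consistency; the
exact choice of statistic at the pathway level is a design decision the
underlying procedure leaves open, so a Wilcoxon rank-sum alternative is
available behind `method="wilcoxon"`. P values are reported nominally
(significance flag at P < .05); a Benjamini–Hochberg column is emitted
for information only. P values below 1e-300 are clamped and flagged, so
ranking by −log₁₀P equals ranking by ascending P. Constant columns get
P = 1 with a flag.

## Module discovery

Run on the pathway score matrix:

1. **Controls only**, build the unsigned soft-threshold adjacency
   a_ij = |PCC(col_i, col_j)|^β (β = 6 by convention), then the
   topological overlap matrix
   TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij).
2. Average-linkage hierarchical clustering on 1 − TOM with a *static*
   cut at 0.99 of the tallest merge height (a full dynamic tree cut is
   out of scope; the static cut plus eigenvector merging reproduces the
   minModuleSize/mergeCutHeight behaviour being tuned). Branches of size
   ≥ minModuleSize become modules; the rest is the unassigned ("grey")
   set. Modules whose eigenvector |correlation| ≥ 1 − mergeCutHeight are
   merged iteratively until stable (absolute correlation, consistent
   with the unsigned network).
3. Each module's **eigenvector** is the first left singular vector of
   its standardized member columns (full-sample mean/SD; standardization
   makes the summary scale-free across pathways), unit norm, sign
   aligned so its correlation with the mean standardized column is
   non-negative. The convention is deterministic and equivariant: negate
   every column and the eigenvector negates.
4. Phenotype association per module: two-sided Wilcoxon rank-sum on the
   eigenvector, exact null when both groups ≤ 25 and tie-free, normal
   approximation with tie correction otherwise.
5. **Explanatory fraction** per module: the largest share of member
   pathways whose proper ancestor sets (ontology root excluded — a
   generic root would make the statistic trivially 1) contain one common
   term; ties go to the lexicographically smallest ancestor id. Members
   absent from the ancestry map cover nothing but count in the
   denominator.
6. `(minModuleSize, mergeCutHeight)` is selected on a grid to maximise
   `Mean_Fraction`, the mean explanatory fraction over *assigned*
   modules (the grey set is excluded — including it would reward
   degenerate clusterings). Ties prefer the larger minModuleSize, then
   the smaller mergeCutHeight. No numeric grid is canonical; the
   defaults (sizes {5, 10, 15}, heights {0.1, 0.2, 0.3}) are this
   package's choice. At the selected point, eigenvectors and Wilcoxon
   tests are recomputed on the full sample.
7. `significant_modules` filters at Wilcoxon P < α (0.05) and fraction ≥
   `min_fraction` (0.5), ordered by ascending P.

Module ids `ME1, ME2, …` are ordered by size; labels carry no cross-run
identity.

## Synthetic data

The generator emits the study conditions every test runs under. Default
cohort: 200 samples (balanced), 60 pathways × 25 genes × 2 features
(~3000 mapped features) plus 150 strictly-unannotated and 150
loosely-annotated unmapped noise features; 5 planted pathways shift 30%
of their features by 1.0 SD in cases; within-pathway exchangeable
correlation 0.3. Features are Gaussian with unit variance —
every statistic in the pipeline (PCC, logistic regression, SVD, rank
tests) is distribution-generic — with an optional logit-link beta mode
that squashes values into (0,1) for methylation-style realism. Balanced
classes mirror a matched case–control design.

Module blocks add a shared latent factor (optionally phenotype-shifted)
to the pathway factors of a block and give those pathways one common toy
ancestor, so clustering, coherence scoring and association testing can
be validated against a known ground truth; `make_pathway_scores`
generates the same planted-block structure directly at the
pathway-score level for tests that exercise module discovery in
isolation.

What the generator does *not* emulate: probe chemistry and array
artefacts, batch effects, cell-composition confounding, population
structure — all of which real studies handle upstream of this tool.
Passing tests therefore demonstrate correctness of the algorithms under
clean planted-signal conditions, not robustness to those artefacts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at B = 1
stage-1 repetition, 5 outer folds × 1–2 repetitions, with the default
200 × 3300 cohort and ridge learners at both stages; the baseline grid
is {500, 1000, 2000}; null calibration uses 10–20 label permutations.
These sizes were chosen so the full distribution of checks completes in
minutes on a single CPU while leaving every statistical conclusion
(chance-level nulls, calibrated type-I rates, planted-signal and module
recovery) clearly resolved.

## Known limitations

* Ranking P values on stage-1 score columns are computed against the
  same labels the scores were trained on (out-of-fold or not); they are
  anti-conservative under the null — in permutation experiments the
  nominal .05 test rejects at roughly 0.17–0.20, independent of B. They
  order the pathways (their intended use) but are not valid inferential
  P values; the nested cross-validation AUC is the leakage-safe summary
  of predictive signal. The ranking test itself is well calibrated on
  label-independent columns.
* Pathway overlap: a feature mapping to several retained pathways is
  duplicated into each, so pathway scores are not independent evidence;
  the ranking should be read accordingly.
* Stage-1 compression can lean on a few strongly associated features,
  diluting the biological specificity of a pathway score relative to its
  nominal gene set.
* Larger pathways are more likely to contain predictive features and can
  skew rankings; no size adjustment is applied.
* The greedy de-correlation is order-dependent by design (most
  outcome-associated column wins); it does not find a globally optimal
  low-correlation subset.
* The static tree cut is a deliberate simplification of dynamic
  hybrid tree cutting; very unbalanced dendrograms may be cut
  sub-optimally.
* Gene matching is exact and case-sensitive; identifier normalisation
  must happen upstream.
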
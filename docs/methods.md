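# Methods

## The modeling problem

A translational drug-response model is trained entirely in vitro — gene
expression of cell lines against their ln(IC50) for one drug — and then
applied to the expression profiles of patients treated with that drug, to
predict a binary responder / non-responder outcome. Because training and
test data come from different worlds (cell cultures vs tumors, different
platforms and normalizations), every such model is really a *pipeline*:
response transformation, train/test homogenization, feature filtering,
feature preprocessing, and a regression algorithm. `tdrscan` treats the
pipeline, not the algorithm, as the unit of analysis and scans the full
Cartesian product of stage options (5·7·4·4·7 = 3,920).

Stage order is fixed: select all cell lines with a measured response for
the drug (all tissues) → remove every gene name occurring more than once in
either matrix (all of its rows; duplicated names are ambiguous probes, not
averageable measurements) → intersect gene sets (train order) → transform
the response → homogenize → filter features → preprocess features → fit →
predict the cohort → orient scores → evaluate. Homogenization precedes
feature selection, so filters see corrected values.

## Response transforms

Continuous targets stay on the ln(IC50) scale (lower = more sensitive):
identity; natural log with an offset of (−min + 1) applied whenever
min(y) ≤ 0 (the offset rule is stated for negative minima; we extend it to
an exact zero minimum, which would otherwise hit log 0); and a Box-Cox
power transform with maximum-likelihood exponent, same offset rule.
Binary targets encode the sensitive class as 1: a median cutoff (ties at
the median are sensitive — deterministic and conservative), and 1-D
2-means. The 2-means problem is solved *exactly* by scanning the n−1
contiguous splits of the sorted values (optimal 1-D k-means clusters are
contiguous), which removes any dependence on initialization; the `seed`
argument is accepted for interface uniformity only.

## Homogenization

All methods operate on the (train, test) pair with the batch variable
fixed to that binary contrast; no other covariates.

* **quantile** — pooled quantile normalization: the reference is the mean
  sorted vector over *all* samples of both sets (symmetric in the two
  origins; a train-only reference is a flag on the standalone function).
  Post-condition, exact: every sample's sorted vector equals the reference.
* **limma-style linear fit** — per gene, remove the fitted batch term and
  restore the pooled mean; equal n makes both batch means the pooled mean.
  Post-condition, exact: per-gene batch means equal. A constant added to
  one batch is absorbed into the batch term, so outputs change only by a
  single global constant (no gene- or sample-specific leakage).
* **combat** — two-batch parametric empirical-Bayes adjustment: per-gene
  standardization on the batch-design fit, normal prior on batch
  locations, inverse-gamma prior on batch scales, method-of-moments
  hyperpriors, iterative joint solution, back-transformation. Our
  implementation reproduces the Bioconductor reference element-wise to
  ~1e-6 on a frozen fixture (tests/data/combat_*_synthetic.tsv). Note the
  EB shrinkage removes the *systematic* batch shift but retains roughly
  half of the per-gene batch-mean sampling noise, so the residual per-gene
  gap scales like sqrt(2/n) — a property of the method, not a defect.
  Zero-variance genes cannot be standardized and pass through with a
  warning.
* **ruv** — PCA on the pooled housekeeping-gene (negative-control)
  submatrix; each gene is regressed on the first k = 10 component scores
  and replaced by its residual (gene mean restored).
* **ruv4** — the SVD formulation: factors from the singular vectors of the
  centered control submatrix, loadings by least squares, corrected data =
  data − Wα. In this two-matrix setting with equal k the two RUV variants
  span the same factor space and therefore coincide up to numerics; both
  guarantee residuals orthogonal to the estimated factors. Both require
  ≥ 2 controls in the shared gene set and k < pooled sample count.
* **yugene** — per-sample cumulative-proportion transform: with values
  sorted descending, rank r maps to 1 − cumsum(r)/total ∈ [0, 1).
  Scale-invariant within a sample; requires non-negative input (ties
  broken by gene index). The standalone function raises on negative
  values; inside a scan, log-scale data with an incidental negative entry
  is min-shifted first so one stray value does not void 560 pipelines.

## Features and models

The variance filter drops the ⌊20%⌋ least variant training genes; the
p-value filter drops the ⌊20%⌋ of genes with the highest two-sided t-test
p-values between the most sensitive and most resistant training samples
(the two classes for binary targets, the top/bottom 25% by transformed
response for continuous ones — the extreme fraction is configurable).
Filters and the gene-wise z-score statistics use training data only and
are applied unchanged to the test side (no test-set leakage; a flag
switches to per-set statistics for the sample-wise z-score, which is
self-referential by definition). PCA is fitted on training samples
(centering + rotation, first 10 components, reduced with a warning when
the training rank cannot support them) and projects both sides.

All seven learners are numeric regressions behind one fit/predict
contract; binary targets are regressed on their 0/1 codes, which keeps a
continuous score for ROC analysis. Lasso (α = 1) and elastic net
(α = 0.5) choose λ on a 30-point log path by 10-fold cross-validation;
ridge chooses its penalty by the efficient leave-one-out form of
cross-validation (the closed-form SVD identity) — a deliberate trade
against refitting 250 models per pipeline in a 3,920-pipeline scan. The
forests mirror the two common R implementations' defaults: 500 trees with
mtry = p/3 versus 10,000 trees of unlimited depth with mtry = √p; both
tree counts are configurable (`ModelParams`) and large scans in the test
suite use 25/50 trees, which trades only prediction variance. SVR uses a
radial kernel with the default bandwidth heuristic. Continuous-target
predictions are negated before evaluation so that "higher score = more
likely responder" holds for every pipeline.

## Evaluation

ROC AUC is computed in its Mann–Whitney form, U/(n₁·n₀) with average
ranks, which is exactly the "ties count one half" pair-counting
convention; the test suite checks it against both exhaustive brute-force
pair counting and scikit-learn. PR AUC is the step-interpolated average
precision (constant scores ⇒ positive prevalence). The separation test is
a pooled-variance two-sided t-test (Welch behind a flag); two degenerate
constant groups yield p = 1 when equal and the smallest positive float
when separated. Pipelines are ranked 1 = best with average ranks on ties
(two tied best pipelines both rank 1.5).

## Scan engine

`run_scan` memoizes stage outputs shared between pipelines (homogenized
matrices; filtered gene sets; preprocessed feature blocks — keyed by the
response transform only where the p-value filter makes them depend on it).
Because every stage is a deterministic pure function of the configuration
and seed, memoization cannot change results; workers receive whole
homogenization groups so caches never cross process boundaries, making
results bit-identical for any worker count and config order. Stage
failures (e.g. RUV with too few pooled samples) are captured into the
result row with the exception text, never silently dropped. Per-stage
seeds derive from the pipeline seed through `numpy.random.SeedSequence`
with fixed stage keys.

The in-vitro baseline (`crossvalidate_cell2cell`) splits the responding
cell lines into k = 5 seeded folds; held-out truth is binarized by the
pipeline's own binarization rule, or by a median split for
continuous-target pipelines so ROC stays well defined. Single-class folds
are skipped with a warning. The transfer experiment splits cell lines
60/20/20 into train/validation/test, trains every pipeline on the training
part, selects the top n (default 300) by validation AUC, and compares the
top subset against all pipelines by two-sided t-tests on the test split
and on the patient cohort.

## Synthetic data

The generator emulates the statistical skeleton of the
cell-screen-to-cohort setting: per-gene Gaussian baselines (mean 7, sd 2 on
a log-expression-like scale, per-sample sd 1); a set of signal genes whose
centered expression drives a latent sensitivity through fixed weights
(scaled so the latent variance equals `effect_size²` independent of the
gene count); housekeeping genes with zero weight; a landmark subset
containing a configurable share (default one half) of the signal genes so
the landmark filter can help or hurt by construction; per-drug responses
ln(IC50) = intercept − [f·s + (1−f)·s_d] + Gaussian noise, where s is the
shared sensitivity factor, s_d a drug-specific factor and f the
`shared_fraction` (expected cross-drug correlation of noiseless responses:
f²/(f² + (1−f)²)); patient expression equal to fresh draws from the same
clean model plus per-gene additive (sd 1) and multiplicative (sd 0.1)
batch offsets; responder = latent sensitivity above the
(1 − responder_fraction) cohort quantile, computed on the *clean* patient
expression. Default cohorts have 24 patients with a balanced responder
split, matching the small-cohort regime the robustness analyses target.
When the latent degenerates (effect_size = 0) responder labels become a
balanced random draw — independent of expression by construction, which is
the null the calibration tests require. A configurable fraction of filler
gene ids is duplicated (independent re-measurements under the same name) to
exercise duplication handling.

What the generator does *not* emulate: platform/probe-level effects,
heavy-tailed or bimodal expression, tissue-specific structure, missing
values, or nonlinear response surfaces. Passing tests therefore show the
machinery is correct and calibrated under a Gaussian linear world, not
that any pipeline will perform comparably on real cohorts.

## Robustness analyses

The random-response null scores the cohort with i.i.d. Bernoulli(½)
vectors ("randomly generated", not permuted — a label-permutation variant
sits behind a flag); the AUC of a binary score vector is computed in
closed form from the 2×2 table. The gene-permutation null shuffles the
cohort's gene ids (values untouched) and re-runs the complete test-side
pipeline per permutation — costlier than reusing fitted models but
faithful to "apply the pipeline to a permuted patient object". The
drug-specificity scan trains a seeded uniform sample of pipelines (default
100) with every drug of the screen and reports the administered drug's
average rank by mean AUC. Setting enrichment takes the best
⌈5%⌉ of pipelines by AUC (ties by average rank, then stable order) and
computes one-sided hypergeometric tail probabilities per stage option,
flagged at α = 0.01, alongside each option's mean AUC.

## Design choices where the design was open

* Survival median-splits assign ties at the median to the non-responder
  class (deterministic, conservative).
* Duplicate gene names are removed entirely, never collapsed by averaging.
* The quantile reference uses both sets, not train only.
* RUV's factor count defaults to k = 10 for both variants.
* Cell2cell truth for continuous-target pipelines is binarized at the
  held-out median.
* Train/validation/test proportions default to 60/20/20.
* The top-set boundary in enrichment uses the average-rank cut.
* The transfer experiment's "confounded cohort" in the test suite mirrors
  every patient profile once per class, making expression carry exactly
  zero information about response: the cleanest construction of an
  outcome driven by an unmeasured factor, and one that keeps the
  top-vs-all comparison on the patient surface deterministic. SVD-based
  stages are excluded from that particular grid because floating-point
  noise in the factor estimation breaks exact prediction ties between
  mirrored patients.

## Problem sizes and numerics

The test suite and the reproduction script run the full 3,920-pipeline
grid on a 200-gene, 80-cell-line, 30-patient synthetic pair with forests
reduced to 25/50 trees; other analyses use 120–600 genes and 20–200 cell
lines (up to 400 per batch where a contract is measured against the
sqrt(2/n) sampling-noise floor). These sizes were chosen so that each property under test (grid
combinatorics, calibration, determinism) is measured at adequate
precision while a complete run stays in the minutes range on one core.
Convergence: the ComBat EB iteration stops at a relative change of 1e-4;
coordinate-descent learners run up to 5,000 iterations with convergence
warnings suppressed inside scans (a non-converged fit is still a valid,
deterministic pipeline member). Ties everywhere (ranks, filters, sorts)
break by stable order to keep runs reproducible.

## Known limitations

Two-batch correction only (no multi-batch designs); no probe-level or
platform modeling; the ridge penalty rule differs from the automatic
estimator used by the R package the pipeline grid mirrors; hyperparameters
beyond λ are fixed by design; no confidence intervals on AUC. The
enrichment and transfer t-tests treat pipelines as independent, which they
are not — between-pipeline correlation makes those p-values
anti-conservative. That caveat applies equally to the original analyses
this package systematizes; interpret the p-values as descriptive ordering
devices, not calibrated error rates.
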
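# Methods

This note documents the models, conventions and numerical choices behind
`sfmetab`, and what the synthetic-data experiments do and do not show.

## Problem setting and conventions

The input is a samples × bins intensity matrix: rows are patients, columns
are NMR metabolite bins (integrated chemical-shift intervals, labelled with
a metabolite name and the ppm center of the interval). Each patient carries
a diagnosis label in {OA, RA}. One global coding is used everywhere:
**OA → 0, RA → 1**, and RA is the positive class of every classification
metric. All matrices are oriented samples-in-rows; MetaboLights
metabolite-assignment files (bins-in-rows) are transposed on read.

Column cleaning on read drops any bin with a missing value, non-numeric
content, or zero variance. This is a deliberately conservative,
reproducible operationalization of "insufficient information"; cleaning is
idempotent.

## Normalization and scaler selection

Five column-wise scalers are implemented exactly as their names suggest:
Z-score `(x−μ)/σ`, min–max `(x−min)/(max−min)`, max-absolute `x/max|x|`,
robust `(x−median)/IQR` (25th–75th percentile), and median + Pareto
`(x−median)/√σ` (median centering followed by Pareto's square-root-of-SD
denominator). SDs use the sample (n−1) denominator throughout the package.
A scaler that hits a zero spread denominator raises an error naming the
offending bin; during selection such a scaler is skipped with a warning.

The winning scaler maximizes the **silhouette score with the known OA/RA
labels as the cluster assignment**, Euclidean distance in the full scaled
bin space. Label-based silhouette was chosen because the quantity of
interest is precisely how well patients separate by diagnosis; an
unsupervised 2-means variant is available behind a flag for sensitivity
analysis. Ties break by the fixed method order (zscore, minmax, maxabs,
robust, median_pareto). PCA (mean-centering only, no re-scaling — the
scaling decision was already made) reports per-component variance fractions
for exploration; it takes no part in classification.

## PLS-DA

PLS-DA regresses the 0/1 class code on the scaled bins with a
deflation-based (NIPALS) PLS fit, 2 components by default (configurable; a
2-D latent space is the usual visual diagnostic at this cohort size). A
single-column 0/1 response, rather than a one-hot pair, makes the per-bin
signed coefficient well-defined: negative ⇔ elevated in OA, positive ⇔
elevated in RA (a consequence of the OA=0/RA=1 coding; relabelling the
classes negates every coefficient). Top-k rankings per class sort by
coefficient with bin-id lexical tie-breaks, flagged when coefficients are
tied or all zero. VIP scores and permutation validation are out of scope.

## Decision-stump screen

For each bin the stump sweeps candidate thresholds at the midpoints of
consecutive sorted unique values (the two degenerate all-one-side cuts
score 0 by convention) and both polarities, scoring with
`MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, defined as 0
whenever a denominator factor vanishes (the random-guess value). Among
equal-MCC candidates the threshold with the largest margin (half the gap
between the flanking values) wins — deterministic and matching the visual
mid-gap boundary one would draw on a 1-D scatter. The screen's *perfect
set* is the bins reaching MCC = 1.0 (tolerance 1e−9); downstream
multivariate modelling uses the complement, since perfectly separating bins
need no model.

Separation metrics per bin: centroid distance `d = |mean_OA − mean_RA|`,
per-class SDs (n−1), the three-sigma verdict `(3·sd_OA < d) ∧ (3·sd_RA <
d)`, and the Fisher discriminant ratio `FDR = d²/(sd_OA² + sd_RA²)`. The
within-class variance is the *sum* of the two class variances (not a
count-weighted pooled variance); with summary statistics rounded to two
decimals this is the reading that reproduces published reference values
within rounding error, and it is the convention tested here.

## SVM-RFE

RFE fits an SVM with a linear kernel (C = 1.0, fixed and documented rather
than tuned — the elimination *ranking* is insensitive to moderate C at
these sizes) and removes the single bin with the smallest squared weight
per iteration. Because one-at-a-time elimination is nested, the package
computes the full elimination order once and treats any retained-set size
as a prefix; this is mathematically identical to running RFE separately per
size and makes GA fitness evaluation affordable (one RFE pass per dataset
instead of one per individual).

## Random forest and LOOCV

The forest hyperparameters are the retained-set size `N_RFE` plus number of
trees `N_est`, maximum depth `D`, minimum samples per split `Sp`, minimum
samples per leaf `Lf`, the per-split feature-subset rule `N_f` (an explicit
count, ⌊log₂ N⌋, or ⌊√N⌋) and the split criterion (gini / entropy /
log_loss; `log_loss` is the entropy-family impurity for classification
trees — the two are mathematically equivalent up to a constant factor).

Evaluation is leave-one-out: n folds, each forest trained on n−1 samples,
and all six metrics (MCC, accuracy, precision, recall, F1, ROC-AUC)
computed **once on the pooled held-out predictions**; ROC-AUC uses pooled
held-out RA probabilities, since a per-fold AUC is undefined for
single-sample folds. Per-fold forest seeds derive deterministically from a
master seed (NumPy `SeedSequence`), so a fitness evaluation is exactly
reproducible and cacheable.

## Genetic algorithm

Fitness is `MCC¹⁵ · N_RFE²`, clamped to 0 for negative MCC (the odd
exponent would otherwise produce negative fitness and break
selection-weight normalization). The 15th power concentrates selection on
MCC-1.0 models — an MCC-1.0 individual weighs (1/0.9)¹⁵ ≈ 4.86, i.e. about
five, times an MCC-0.9 individual at equal `N_RFE` — while the quadratic
term rewards retaining more bins.

One generation: fitness-proportional weights (uniform when all fitness is
zero) select parent pairs with replacement; crossover swaps exactly two
hyperparameter slots chosen uniformly without replacement; this repeats
until `N_pop − 2·N_elite` offspring exist (96 at the default population of
100 with 2 elites). One copy of each elite joins the offspring in the
mutation pool — each member there mutates one slot with probability 0.90 —
and a second, pristine duplicate of each elite is appended unchanged,
restoring `N_pop` members and guaranteeing a monotone best-ever fitness.
The description this follows admits two readings of which members mutate;
the accounting that sums 96 + 2 + 2 = 100 is the default and the
alternative (elites fully exempt from mutation) is a config switch.
Evaluations are cached by the full hyperparameter tuple, which also makes
"unique combinations explored" a countable quantity.

The default search grids (N_RFE 5–195 step 5; N_est 25–1600; D 2–12; Sp
2–24; Lf 1–12; five `N_f` rules; three criteria) are this package's own
choice: wide enough for >12 million combinations while containing the
reference optimum (N_RFE=50, N_est=100, D=6, Sp=10, Lf=6, ⌊log₂⌋,
log_loss). A reduced space (modest forests, single criterion, 96
combinations) serves quick runs and tests.

## Shapley attribution

The explained output is the forest's RA probability, so "positive ⇒
promotes RA" holds by construction. Attributions use the path-dependent
conditional expectation: a coalition that omits a split feature follows
both children weighted by their training cover. For one tree this value
function is additive over leaves, and each leaf's term depends only on the
distinct features on its root path; grouping path nodes by feature gives,
per feature, a 0/1 "sample satisfies the path constraints" indicator and a
cover-ratio product. The Shapley value of each leaf term is then an
elementary-symmetric-polynomial sum over the path features — exact,
polynomial-time, no sampling. Ensemble values average over trees; **local
accuracy** (base + Σ attributions = predicted probability) is asserted for
every explained sample at 1e−6. The implementation is validated against
brute-force subset enumeration over the same value function on small
models. Attribution runs in-sample with the final model trained on all
samples (a per-fold variant would explain 24 different models, not the
deployed one). Each bin's direction label is the sign of the correlation
between its intensity and its attribution.

Marker comparison collapses bins to metabolite names, then reports
per-disease overlap and unique sets between the PLS-DA and ML selections;
the *ambiguous* set is the intersection of the OA-associated union with the
RA-associated union across both methods, and is invariant to swapping the
method labels.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with defaults
fixed at the study-shaped conditions: 10 OA + 14 RA samples, 200 bins —
4 *perfect*, 50 *informative*, 146 *null* — positive intensities, and two
bins per synthetic metabolite name (so metabolite-level set algebra is
exercised).

- **Perfect bins** draw the two classes from uniform distributions on
  disjoint intervals with a normalized gap of at least 0.5 on a random
  positive scale, so a stump reaches MCC 1.0 regardless of scaling (stump
  results are invariant under monotone transforms).
- **Informative bins** are class-conditional Gaussians whose means differ
  by `effect_size · noise_sd` (default 2.0 pooled SDs), drawn
  **conditional on the realized class supports overlapping** (rejection
  sampling). The conditioning is part of the definition of "moderately
  informative": at n = 24 an unconditional 2-SD shift separates completely
  by chance in a few percent of draws, which would blur the
  perfect/informative distinction the screen is supposed to recover. With
  it, the perfect set equals the planted perfect set by construction
  (a null bin separating by chance has probability ≈ 2/C(24,10) ≈ 10⁻⁶ per
  bin).
- **Null bins** share one Gaussian across classes. `inject_correlation`
  rebuilds consecutive blocks of null bins from a shared-factor model with
  pairwise correlation ρ, leaving labels and planted bins byte-identical.
- Positivity comes from a global shift, not truncation, preserving every
  distributional shape. A single seeded generator stream makes identical
  configs byte-identical.

What passing on synthetic data shows — and does not. The generator matches
the *dimensions and separation structure* of real binned NMR data, not its
chemistry: real bins are correlated through pathways and peak overlap
(only optionally and crudely emulated), intensities are heavy-tailed and
heteroscedastic rather than Gaussian, and real "perfect separation" at
n = 24 may be a small-sample artifact rather than a population property.
Pipeline recovery of planted structure therefore validates the
implementation and the method's behavior under its own assumptions; it is
not evidence about any particular clinical cohort.

## Problem sizes and budgets

Tests exercise the full default cohort shape (24 × 200). The
parameter-recovery experiment runs the GA at population 20 for 5
generations over the reduced space on 10 seeded cohorts, and the RFE
contrast evaluates the tuned-model defaults with and without RFE on the
same 10 cohorts — sizes chosen so the whole suite runs in minutes on one
CPU while still covering every stage end to end. The acceptance script
reconstructs the reference Fisher discriminant ratios from published
summary statistics and is instantaneous.

## Known limitations

- LOOCV metrics pool predictions across folds; per-fold metric variance is
  not reported.
- The SVM-RFE ranking assumes near-linear separability (which the PCA/
  silhouette stage is meant to establish); heavily nonlinear structure
  would demand a different eliminator.
- The GA's search-space grids are a design choice, not a canonical set;
  conclusions about "combinations explored" depend on them.
- `read_maf` covers the common tab-separated metabolite-assignment layout
  (name column plus per-sample intensity columns, optional chemical-shift
  column); exotic MAF dialects are not handled.
- Attribution is path-dependent (cover-weighted); interventional
  attributions against an explicit background distribution are not
  implemented.
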
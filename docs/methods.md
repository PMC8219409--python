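# Methods

This note documents the models and procedures implemented in `gainselect`,
the parameter choices that matter, and what the synthetic cohort does and
does not establish.

## Cohort model

A cohort is a rectangular table: one row per pregnancy, one column per
maternal feature, and a binary outcome (1 = preterm birth, the positive
class; 0 = term birth).  The bundled default schema has 36 columns — a
patient identifier (`PID`), 34 candidate features, and the target (`PTB`).
Identifiers are carried through I/O but never scored or modelled.  Missing
cells are accepted on read (empty field or `NA`), kept as NaN, and written
back as empty fields, which makes read∘write the identity on valid
datasets.  How the source records encoded date-like fields (last menstrual
period, delivery dates) is unknown; the schema types them as categorical
and the generator emits small integer codes for them.

## Preprocessing

**Imputation.** Missing values in numeric features are replaced by the
observed mean of that feature; the mean is undefined for
ordinal/binary/categorical features, so those use the mode (ties broken
toward the smallest value — a deterministic, if arbitrary, convention).
Observed cells are never altered, so the column mean of a numeric feature
is invariant under imputation.  Imputation runs before discretization, in
that fixed order.

**Discretization.** Continuous features are mapped to ordinal interval
codes 0..k−1 by ascending cut points with half-open intervals [a, b): a
value equal to a boundary goes to the upper bin.  Outer intervals are
open, so every finite value receives exactly one code, including values
outside the fitted range.  Three fitting methods are provided:

- `equal_width` / `equal_frequency` (unsupervised, `bins` ≥ 2, default 5;
  bin count is clamped with a warning when it exceeds the number of
  distinct values; a constant feature yields a single bin);
- `mdl_entropy` (default): recursive binary splitting that picks the cut
  minimizing weighted child class entropy and accepts it only when the
  information gain exceeds the minimum-description-length cost of encoding
  the split (Fayyad–Irani criterion).  It chooses its own number of cuts.
  This supervised, information-theoretic discretizer is the package's
  default because the pipeline's downstream scoring is itself
  entropy-based; the "minimum information loss" discretizer referenced in
  prior literature is defined only there and is out of scope.

Applying a fitted map to an already-discretized cohort is the identity
(the dataset carries a `discretized` flag), making dataset-level
discretization idempotent.

## Feature selection

Information gain is computed in bits with the conventional signed entropy
−Σ p log₂ p and the 0·log 0 ≡ 0 limit.  The selector:

1. partitions the rows into three disjoint, exhaustive, **stratified**
   subsets of equal size ±1, driven by an explicit seed (how the original
   study partitioned its data is unstated; stratification guarantees each
   subset sees both classes);
2. scores every candidate feature independently within each subset (gains
   are never pooled across subsets);
3. computes the range threshold r = (max gain − min gain)/n, where n is
   the number of candidates actually scored — identifiers and the target
   are excluded, since an identifier column carries maximal spurious gain
   and would corrupt the range;
4. removes features with gain **strictly below** r (a gain exactly equal
   to r survives, reading the removal rule literally), and
5. returns the union of the three survivor sets.

Consequences worth knowing: the threshold cut is monotone in gain (every
removed feature scores below every kept feature within a subset); a
one-class subset makes all gains zero and r = 0, so nothing is removed
(flagged with a warning); and when all gains tie, everything survives.
The union rule makes selection permissive — a feature needs one good
subset out of three — which on noisy data keeps a handful of spurious
features alongside the truly informative ones.

Selection runs by default on the full preprocessed dataset before the
train/test split, mirroring the staged workflow the pipeline reproduces;
this leaks target information into the feature choice, so a
`select_on_train` option restricts scoring to the training partition for
leakage-safe use.  Likewise `compute_gain` warns when a feature looks
continuous (more distinct values than half the rows), because
fragmentation inflates gain.

## Class balancing

The minority class is oversampled to a target share (default 0.5) by
SMOTE: each synthetic row is a uniform interpolation between a random
minority row and one of its k = 5 nearest minority neighbors (Euclidean
distance on the ordinal codes), with interpolated coordinates rounded
half-up to valid codes so synthetic records stay in the discretized
domain.  Synthetic rows therefore lie coordinate-wise within the minority
min–max envelope, majority rows are never added or removed, and a fixed
seed gives bit-identical output.  k is clamped to (minority size − 1) with
a warning when the minority class is small.  A `duplicate` mode replicates
minority rows verbatim instead, for the reading of balancing as plain
replication.  Balancing the *full* dataset before the split (`full`
mode) copies synthetic information into the test set and flatters
accuracy; the default `train-only` mode balances only the training
partition after the split.  Both are supported and logged because the
pipeline exists partly to study that difference.

## Classification and evaluation

The cohort is split 70/30, stratified, with the train size defined as
round(0.7·n).  Three interchangeable classifiers are trained via
scikit-learn: a CART decision tree, L2-penalized logistic regression
(max_iter = 1000), and an RBF-kernel SVM.  No study-specific
hyperparameters exist to reproduce, so the delegate defaults are used,
pinned and echoed into every run manifest.

Evaluation counts the confusion matrix with preterm = positive and
derives: CCR (accuracy, percent scale), TPR/sensitivity, TNR/specificity,
FPR, FNR, precision, recall and F1.  Recall is TP/(TP+FN), identical to
TPR.  A metric with a zero denominator is reported as NaN and named in
`undefined_metrics`, never coerced to zero.  The constant majority-class
baseline accuracy is always logged next to the model metrics rather than
asserted against, since a classifier can legitimately fall below it on a
balanced test set.

All randomness in a pipeline run flows from one root seed, split per
stage (`partition`, `split`, `balance`, `model`, `simulate`) through
`numpy.random.SeedSequence`, so a single integer reproduces every
artifact.

## Synthetic cohort

The generator emulates the *shape* of the target data: 1300 records, 36
columns, 23.8% minority prevalence by default, mixed binary/ordinal/
binned-numeric candidates.  Six features (`GA`, `BP`, `HB`, `PE`, `HT`,
`PCS`) are planted as informative with fixed per-class discrete
distributions; the remaining 28 candidates are class-independent noise.
The planted distributions were chosen analytically so each carries at
least 0.1 bits of population information gain at the default prevalence —
comfortably above both the range threshold (~0.007–0.009 bits in a
~433-row subset) and the small-sample gain bias of the noise features
(≈ (V−1)/(2n ln 2) bits for a V-level feature) — and `expected_gain`
computes that closed-form population gain exactly, giving convergence
targets for sample gains.  Features are drawn class-conditionally
independent and pre-binned; `raw_mode` adds Gaussian jitter (σ = 0.25) to
numeric features so the discretizer has real work, and `missing_rate`
injects uniform missingness into candidate cells.

What passing tests on this cohort do **not** show: the default
distributions are fixtures, not estimates of clinical reality; features
are conditionally independent (no comorbidity correlation structure); and
recovery results quantify the selector's behavior under planted,
well-separated signal, not its clinical validity on real obstetric
records, which remain private to the original study sites.

## Numerical choices and degenerate inputs

- Entropy/gain tolerances: gains match a first-principles oracle to
  1e−12; bounds 0 ≤ Gain ≤ Entropy(S) ≤ log₂ c hold up to 1e−12 slack.
- Discretization boundary ties go to the upper bin; MDL split ties keep
  the first (leftmost) minimizing cut.
- A constant feature has gain exactly 0 and a single-bin map; an empty
  instance set has undefined entropy (error, not 0).
- Balancing a cohort already at/above the target share is a no-op;
  `(target·n − m)/(1 − target)` synthetic rows, rounded, land the
  minority share within two percentage points of target.
- Mode imputation ties break to the smallest value; interpolation
  rounding is half-up (`floor(x + 0.5)`).

## Known limitations

- The three-subset count is fixed by design of the workflow being
  reproduced; the package exposes `n_subsets` but makes no claim that 3
  is optimal.
- The range threshold is scale-free but sensitive to the single maximum
  gain; one dominant feature raises the bar for all others within its
  subset.
- Default selection-before-split and `full` balancing mode both leak
  information by construction; they exist to reproduce and measure that
  workflow, and the leakage-safe variants are the recommended settings
  for any real analysis.
- Published headline accuracies from the private 1300-patient cohort
  cannot be recomputed here; the pipeline's synthetic results demonstrate
  mechanism (e.g. that balancing typically raises SVM accuracy), not
  those numbers.
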
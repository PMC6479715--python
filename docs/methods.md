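# Methods

## Problem and data model

The package classifies users into the three Internet Addiction Test (IAT)
levels from browsing-history event logs. A log row is one cached or
downloaded file: user id, file name, category code 1–5 (document,
graphic, archive, multimedia, others), size in bytes, and creation
timestamp. Two attributes are derived per record: day-of-week (Monday=1
… Sunday=7) and clock hour. The hour is kept on the full 0–23 range: a
1–23 convention would silently merge or drop the midnight hour, and the
map treats hour as a magnitude either way. Categories may be given
explicitly or derived from the file extension via a shipped, editable
YAML-configurable table; unknown extensions fall to "others". IAT total
scores (20–100) map to levels by Young's cut points: mild ≤ 50, moderate
51–80, severe ≥ 81; the mapping is validated and monotone.

## Per-user SOM signature

One self-organizing map is trained per user — the feature matrix is the
user's individual behavioral signature, so no information flows between
users at this stage. Defaults and rationale:

- **Grid**: 8×8, hexagonal. Hex unit positions are staggered offset
  coordinates (odd rows shifted by 0.5, row pitch √3/2), so planar
  Euclidean distance between unit centers equals hex lattice distance; a
  rectangular topology is available by configuration.
- **Input vector**: (category, day-of-week, hour), each min–max scaled to
  [0, 1]. Only the category carries class signal; the two time attributes
  act as within-user dispersion so that records of one category spread
  over several cells and per-cell tallies reflect the user's category
  *mixture*. With a category-only 1-D input (selectable via
  `attributes=("category",)`) all records of a category are identical,
  every category collapses onto a single best-matching unit, at most five
  cells are ever active and each is trivially pure — the dominant-type
  reduction then carries almost no information and downstream accuracy
  sits at the majority baseline. The multi-attribute default is also the
  only regime in which cells can contain a mix of file types, which is
  what the dominant-type rule exists to resolve.
- **Training**: classical online rule, Gaussian neighborhood kernel
  h = α(t)·exp(−d²/2σ(t)²), α decaying linearly 0.5 → 0.01 and σ linearly
  4 → 1 over training. Weights initialize uniformly inside the
  per-dimension data range from the map's seed. The step count is
  min(epochs × n_records, 10 000) with epochs = 500; the cap keeps
  study-scale featurization (217 maps) around half a minute on one core
  while leaving the maps well converged (quantization error is flat well
  before the cap at these input dimensions).
- **Extraction**: records are assigned to their BMU cells; each cell's
  code is the category with the maximal tally (ties break to the lowest
  code, empty cells code 0). Extraction is order-invariant and tallies
  conserve the record count. The matrix is one-hot binarized (5 bits per
  cell, 320 bits for 8×8); empty cells encode as all-zero blocks, making
  the encoding invertible.

## Base classifiers

Four general-purpose classifiers behind one fit/predict contract, with
fixed documented settings (scikit-learn estimators underneath):

- **SVM**: linear kernel, C = 1, explicit one-against-the-rest; the
  binary machine with the highest decision margin wins.
- **BNC**: Bernoulli naive Bayes with Laplace (+1) smoothing — a
  naive-structure Bayesian network classifier appropriate for the
  all-binary feature distribution.
- **C5**: an entropy-criterion decision tree with minimum leaf size 2.
  This is a documented stand-in for the proprietary C5.0 (gain-ratio
  splitting and confidence-based pruning are not available in the
  underlying library); it is not claimed equivalent.
- **KNN**: k = 3 (matching the three-level label set), Euclidean
  distance on the binary vectors.

Levels are coded 1 < 2 < 3 in severity order, and every tie rule in the
package (vote ties, margin ties, neighbor ties) resolves to the lower
severity — the conservative choice for a screening instrument.
Single-class training data is rejected, as is predicting before fitting
or with mismatched feature dimension.

## Ensemble with CBR fallback

Member votes are weighted by training accuracy, w_i = acc_i / Σ acc_j
(weights conserve to 1). Prediction is two-phase:

1. **Consistency test**: if all four members predict the same level, that
   level is final (mode `consistent`).
2. **CBR resolution**: otherwise the distinct predicted levels — only
   those — become candidates, and the stored training cases of each
   candidate class are searched for the most similar case to the query
   (1-nearest-neighbor retrieval; mean aggregation over the class is
   available by configuration). Similarity is the simple-matching
   coefficient — the fraction of agreeing bit positions — chosen because
   both joint presence and joint absence of an active cell type are
   informative here; Jaccard is available by configuration. The level
   with the highest class similarity wins (mode `cbr_resolved`); exact
   similarity ties fall back to the weighted vote restricted to the tied
   levels, then to lower severity.

An `ensemble_only` switch replaces phase 2 with the plain weighted vote
over all member predictions (mode `voted`), giving the vote-only baseline
for comparison. Case retention (the "retain" step of the CBR cycle) is
implemented but off by default so that evaluation runs are deterministic
and free of test-to-test leakage.

## Evaluation protocol

Users are split 2/3 train / 1/3 test with per-class train counts
round-half-up(2/3 × class size) — e.g. class sizes (114, 91, 12) give
train (76, 61, 8) and test (38, 30, 4) — repeated ten times with
per-repetition seeds, all methods sharing identical splits and identical
fitted members. Metrics are one-vs-rest per level: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, computed in
full precision and rendered to one decimal; the headline "average
accuracy" is the unweighted mean of the three per-level accuracies (this
aggregation reproduces the published average-accuracy rows exactly from
their per-level cells). Both strata must be non-empty or the metric is
reported as an error rather than silently zeroed.

## Synthetic cohort generator

No public dataset of labeled browsing logs exists, so the generator is a
first-class module emulating the structure such a study population
exhibits:

- **Class proportions** default to 114/91/12 out of 217. Allocation is
  deterministic largest-remainder (not multinomial) so the rare severe
  class can never fall below the two-members-per-class minimum the
  stratified split requires.
- **Category mixtures** per level interpolate between a shared base
  mixture and level-specific extremes via a single `separation` knob in
  [0, 1]: 0 makes all levels statistically identical, 1 maximally
  distinct. The extremes encode mild users skewing to documents, moderate
  to graphics, severe to multimedia — a plausible but invented pattern;
  the default separation of 0.8 yields base-classifier accuracies in the
  80–98% range.
- **Timing** is weekend/evening-heavy (70% of records in leisure slots)
  *identically for every level*, mirroring the empirical finding that
  day-of-week and hour do not discriminate addiction levels; timing can
  therefore never leak class information.
- **IAT scores** draw uniformly inside the level's range (no score
  distribution is published); file sizes are log-normal per category;
  record counts per user draw uniformly from a configurable range
  (default 150–250).

What passing tests on this cohort do *not* show: real browsing data has
burstiness, session structure, user-specific site habits, mixed devices
and questionnaire noise (scores near level boundaries), none of which are
modeled. Synthetic results are an internal-consistency check of the
pipeline, not an estimate of field performance.

## Numerical and design choices

- All randomness flows from explicit seeds; a single global seed fans out
  to named stage sub-seeds (cohort, som, split, classifier), and every
  derived seed stays below 2³¹.
- BMU ties resolve to the lowest unit index; dominant-type ties to the
  lowest category code; all label ties to lower severity.
- Validation errors are raised early and name the offending row, class or
  dimension; malformed log rows are collected and reported with 1-based
  line numbers.
- Problem sizes in the test and acceptance runs (cohorts of 36–217 users,
  200 records per user, 10 repetitions) are the package's default
  study-scale conditions; the full suite runs in a few minutes on one
  core.

## Known limitations

- At high mixture separation the linear-SVM member is near-ceiling, and
  on the minority of test users where members disagree the accuracy-
  weighted vote resolves slightly more of them correctly than 1-NN case
  retrieval does; the CBR fallback's advantage over plain voting is
  therefore regime-dependent — it is a property of populations whose base
  classifiers are individually weak, not a structural guarantee. The
  acceptance suite measures both modes on identical splits and reports
  the comparison honestly.
- The C5.0 stand-in is the weakest member on these distributed binary
  signatures (single greedy univariate splits exploit many weakly
  informative bits poorly); the ensemble is robust to this by
  construction.
- The feature matrix discards per-cell tally magnitudes (only the argmax
  survives), an intentional fidelity-losing reduction inherited from the
  method being implemented.
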
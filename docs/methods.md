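# Methods

This note records the models, assumptions, parameter defaults and
numerical choices implemented in `weighttraj`. It makes no empirical
claims beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Data model

An individual is a `ParticipantRecord`: an id, a height in cm, an
optional medication flag, and a list of `(day, weight_kg)` entries with
strictly increasing days. Day 0 is the individual's first entry. The
analysis object is the **daily percent-change series** on days 0..270:
`v[d] = 100 * (w(d) - w(0)) / w(0)`, with `v[0] = 0` by construction and
`np.interp` linear interpolation between entries. Nine months is taken as
270 days; all time frames are `months * 30` days.

### Exclusions (training cohorts)

Applied by `apply_exclusions`, each with a named criterion in the log:

| Criterion | Default |
| --- | --- |
| max daily change between consecutive entries | 1.5 kg/day |
| minimum number of entries | 2 |
| minimum observation span | 270 days |
| minimum height (exclusive: height ≤ threshold excluded) | 100 cm |
| weight-affecting medication | excluded (skippable) |
| first entry within | 270 days |

Validation-style use (`ExclusionConfig.validation_default()`) drops the
span requirement, since validation individuals are deliberately
short-horizon.

### Extrapolation

To impute a nine-month outcome for an individual observed only to day
`L < 270`, the series is extended linearly along the line through the
origin and `(L, v[L])`: `v[d] = d * v[L] / L`. This assumes the average
daily rate of change observed so far persists. It is exact for linear
trajectories (tested to 1e-12) and conservative for saturating ones — it
overstates late change for individuals still in their fast early phase.

## 2. Dynamic time warping

`dtw.py` implements the standard DP recurrence
`D(i,j) = c(a_i, b_j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1))` with
squared local cost and a final square root (default), optional absolute
cost, and an optional Sakoe–Chiba band automatically widened to at least
the length difference. The core is a numba `@njit(cache=True)` kernel
with a pure-python fallback if numba is unavailable. It is verified
against exhaustive enumeration of all monotone warping paths for short
series (acceptance criterion; agreement to 1e-9).

## 3. Outcome classes

`build_cluster_model`:

1. Compute the full pairwise DTW matrix of the training series.
2. Run three hierarchical clusterings on it (scipy linkage: average,
   complete, Ward), cut at k = 5, and align labels across variants with
   the Hungarian algorithm on the contingency table. Individuals on whose
   label all three variants agree are **consensual**; their per-day
   arithmetic means are the initial centroids. (Ward linkage formally
   assumes Euclidean inputs; on a DTW matrix it is used as a heuristic
   vote, which is exactly its role here.)
3. DTW-k-means: assign each series to the nearest centroid by DTW (ties
   to the lowest index), update centroids as per-day arithmetic means,
   iterate to a fixed assignment or `max_iter`. An empty cluster keeps
   its previous centroid and logs a warning. The within-cluster DTW
   objective is recorded per iteration. Note: because centroids are
   arithmetic means rather than DTW barycenters, the objective is not
   guaranteed monotone on unstructured data; on clusterable data it
   decreases (tested on a seeded instance).
4. Order centroids by their day-270 value (most loss first) and name the
   classes `high_loss, moderate_loss, insufficient_loss, low_gain,
   high_gain`; the three-class scheme merges to
   `loss = {high_loss, moderate_loss}`, `gain = {low_gain, high_gain}`.
5. Refit cutoffs on the nine-month percent change so that thresholding
   reproduces the cluster labels with minimum error (exhaustive sweep
   over observed values per adjacent class pair; a value `x ≤ cutoff`
   belongs to the loss side; error ties resolved to the largest cutoff;
   verified against brute force). Published fallback cutoffs
   `(-9.2, -2.4, -0.1, 2.2)` / `(-2.4, -0.1)` are used when no refit is
   possible.

## 4. Prediction

**Time frames**: 0.5, 1, 2, 3, 4, 5, 6, 7, 8 months (end days 15..240).
`select_frame` picks the frame whose end day is nearest to the
individual's last entry, ties upward (e.g. day 105 → the 4-month frame).
**Eligibility** at a frame: ≥ 2 entries inside it and the last in-frame
entry within 30 days of the frame end. Five-class predictions are
reported only for frames ending after day 120; shorter horizons carry too
little signal to separate five classes and only the three-class call is
returned.

**Feature encodings** (`build_features`):

| Encoding | Vector |
| --- | --- |
| `bmi_last` | baseline BMI, percent change at frame end |
| `bmi_history` | baseline BMI + values at every frame-grid end day ≤ frame end |
| `dtw_dists` | DTW distances to the five class means truncated to the frame |
| `daily` | baseline BMI + all daily values 1..frame end |

**Methods** (sklearn pipelines, standardized where scale matters):
logistic regression (`max_iter=2000`), linear regression, Gaussian naive
Bayes, SVC and SVR with RBF kernels, and `MLPClassifier` with one hidden
layer of 16 units, lbfgs solver and `max_iter=2000` (lbfgs because the
problems are small and low-dimensional; adam needed far more iterations
for the same accuracy). Default encodings: `dtw_dists` for logistic
regression, linear regression and SVC; `bmi_last` for naive Bayes, SVR
and the MLP; the MLP may instead use `daily`. An optional
`select_encoding` sweep picks the encoding maximizing mean CV accuracy.

**Cross-validation**: class-stratified 5-fold; per class the shuffled
members are split by floor division with the remainder dealt round-robin
from fold 0. Regression methods predict the nine-month percent change
and are converted to classes through cutoffs refit on the training folds
only, so no outcome information leaks into the evaluation fold.

## 5. Evaluation

Accuracy plus per-class one-vs-rest sensitivity, specificity, precision
and `F1 = 2TP/(2TP+FP+FN)` from the confusion matrix (fixed class
order). Undefined ratios (0/0) are reported as NaN, never as 0. The
**random baseline** is the Monte-Carlo mean accuracy (default 10,000
seeded replicates) of drawing each individual's class i.i.d. from the
training class distribution; it converges to
`Σ_c p_train(c) p_truth(c)` (tested within 3 standard errors).
`validate_per_frame` scores a trained bundle on an external cohort frame
by frame, restricted to eligible individuals; the truth label is the DTW
assignment of the day-270-extrapolated series to the training class
means.

## 6. Synthetic cohort generator

Real cohorts of this kind (commercial weight-coaching app data) are not
redistributable, so the generator is the study environment and its
defaults are the study conditions — they were fixed before any results
were inspected and are not tuned to outcomes.

Five archetypes `a * (1 - exp(-d / tau))` with terminal values
−12, −7, −1.5, +1.5, +5 percent and time constants 70, 70, 50, 120, 120
days; these shapes (fast early loss that saturates; slow drift for
gainers) mirror the cluster-mean trajectories the method is designed to
find. Baseline weight ~ U(60, 120) kg, height ~ N(170, 8) cm. Entry days:
day 0 plus distinct uniform later days, the last anchored at the final
day; training default U(10, 62) entries over 270 days,
`n_per_class=(60,)*5`. Per-entry noise is i.i.d. N(0, 0.5) in percent
space (a random-walk mode exists). A repair pass nudges entries so that
consecutive rates stay below 0.95 × the 1.5 kg/day exclusion limit;
`inject_violations` disables it deliberately for stress tests.
`SimConfig.validation_style` produces sparse logs — U(3, 30) entries,
half the cohort truncated at a day ≥ 60 — imitating real app users.

**Realism limits**: archetype membership is fixed per individual (no
mid-course switching, relapse or plateaus-then-drop patterns); noise is
homoscedastic; entry times are independent of trajectory (real users log
less when gaining). Accuracies on this generator are therefore upper
bounds on real-cohort performance, and the acceptance checks are
deliberately qualitative (beats the random baseline, improves with
follow-up length, three-class ≥ five-class) rather than numeric targets.

## 7. Numerical choices and problem sizes

- DTW uses float64 throughout; the numba kernel allocates one
  `(n+1)×(m+1)` DP table (271-day series: ~0.6 MB, negligible).
- Pairwise DTW on a 300-individual training cohort (the acceptance
  default) takes ~15 s on one CPU; training all six methods over nine
  frames and two schemes ~10 s; the whole acceptance run ~30 s.
- All randomness flows from explicit integer seeds (numpy
  `default_rng` / `SeedSequence`; sklearn `random_state`); identical
  seeds reproduce cohorts, folds and reports bit-for-bit (tested).
- Cutoff refitting is an exact exhaustive search over observed values
  per adjacent class pair, O(n²) per pair — trivial at these sizes.

## 8. Limitations

- The linear extrapolation to day 270 biases imputed outcomes for
  strongly saturating trajectories; individuals near a class boundary
  can flip truth labels under a different imputation rule.
- Ward linkage on a DTW dissimilarity matrix has no Euclidean
  justification; it is one of three votes, not a standalone clustering.
- The DTW-k-means objective can oscillate on unstructured data (see
  §3); convergence is declared on fixed assignments, capped by
  `max_iter`.
- Published fallback cutoffs come from a different cohort and are only
  used when refitting is impossible.
- No calibration of predicted probabilities is attempted; `probabilities`
  from classifiers are the raw model outputs.
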
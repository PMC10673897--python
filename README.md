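# weighttraj

Early prediction of nine-month weight-change outcomes from sparse,
self-reported weight logs.

People who track their weight in an app log it irregularly: a handful of
entries in the first weeks, then gaps of weeks or months. `weighttraj`
answers the question *"given what this person has logged so far, which
long-term weight trajectory are they on?"* — early enough (from two weeks
after the first entry) to matter for coaching or intervention.

## The method

1. **Outcome definition by clustering, not by arbitrary thresholds.**
   Each individual's log is converted into a daily percent-weight-change
   series over days 0–270 (linear interpolation between entries). Pairwise
   dissimilarities are computed with dynamic time warping (DTW), which
   tolerates the different paces at which people lose or gain weight.
   Consensus over three hierarchical clusterings (average, complete and
   Ward linkage) seeds a DTW-k-means that partitions the cohort into five
   trajectory classes, ordered from most loss to most gain: `high_loss`,
   `moderate_loss`, `insufficient_loss`, `low_gain`, `high_gain`. Cutoffs
   on the nine-month percent change are then refit so that a single number
   reproduces the cluster assignment as closely as possible; a coarser
   three-class scheme (`loss` / `insufficient_loss` / `gain`) merges the
   extremes.
2. **Per-time-frame supervised prediction.** For each of nine prediction
   time frames (0.5, 1, 2, …, 8 months), six learners — logistic
   regression, linear regression, Gaussian naive Bayes, SVM
   classification and regression, and a small MLP — are trained to
   predict the class from what is observable inside the frame. Feature
   encodings include baseline BMI plus last observed change, the history
   at the frame grid, and the vector of DTW distances to the five
   truncated class means. Accuracy is estimated by class-stratified
   five-fold cross-validation; regression methods convert their
   continuous prediction to a class through cutoffs refit inside each
   training fold.
3. **Eligibility and the random baseline.** An individual is scored at a
   frame only if they have at least two entries inside it and their last
   in-frame entry is within 30 days of the frame end. Every accuracy is
   compared against a random baseline: the expected accuracy of drawing
   classes from the training class distribution.

Real health-coaching cohorts of this kind cannot be redistributed, so the
package ships a synthetic cohort generator whose five archetype
trajectories (saturating-exponential curves with terminal changes of
−12, −7, −1.5, +1.5 and +5 percent) mimic the observed class structure,
with configurable per-entry noise, sparse/truncated validation-style
sampling, and the same plausibility rules (e.g. no more than 1.5 kg
change per day) that the exclusion criteria enforce.

## Worked example (CLI)

Simulate a training cohort and a sparse validation cohort, derive the
classes, train a logistic-regression predictor, and score it:

```
$ weighttraj simulate --out-dir train --seed 7 --n-per-class 40
INFO weighttraj: wrote 200 participants to train
$ weighttraj simulate --out-dir valid --seed 8 --n-per-class 20 --sparse
INFO weighttraj: wrote 100 participants to valid
$ weighttraj cluster --input train/cohort.csv --heights train/heights.csv --out model.json
INFO weighttraj: 200 kept, 0 excluded
INFO weighttraj: consensus fraction 1.000, k-means iterations 1
$ weighttraj train --input train/cohort.csv --heights train/heights.csv \
    --cluster-model model.json --out bundle.joblib --seed 7 --method logistic_regression
INFO weighttraj: trained 18 models
$ weighttraj predict --input valid/cohort.csv --heights valid/heights.csv \
    --bundle bundle.joblib --out preds.csv
WARNING weighttraj: id S0094 ineligible: last entry in frame not within 30 days of day 240
INFO weighttraj: wrote 100 prediction rows
$ weighttraj evaluate --predictions preds.csv --truth valid/truth.csv --out report.json
n = 81   accuracy = 1.000
class                   sens    spec    prec      F1
loss                   1.000   1.000   1.000   1.000
insufficient_loss      1.000   1.000   1.000   1.000
gain                   1.000   1.000   1.000   1.000
```

(The sparse cohort's 19 ineligible individuals are flagged in `preds.csv`
with the failed rule, not dropped silently. With the default noise level
the synthetic classes are well separated, hence the perfect score here;
see `docs/methods.md` on generator realism.)

The prediction CSV carries one row per individual:

```
id,frame_months,eligible,reason,three_class,five_class,dtw_high_loss,...
S0001,,no,last entry in frame not within 30 days of day 240,,,,,,,
S0002,8,yes,,loss,high_loss,1.9706,52.8536,126.9495,165.3226,202.3891
```

## Worked example (Python)

```python
from weighttraj import (SimConfig, generate_cohort, train_bundle,
                        TrainingConfig, predict_individual)
from weighttraj.cohort_io import ParticipantRecord, WeightEntry

cohort, truth = generate_cohort(SimConfig(seed=7, n_per_class=(40,) * 5))
bundle = train_bundle(cohort, methods=("logistic_regression",),
                      cfg=TrainingConfig(seed=7))

rec = ParticipantRecord(id="P001", height_cm=170.0, entries=[
    WeightEntry(0, 92.0), WeightEntry(21, 90.1),
    WeightEntry(55, 88.0), WeightEntry(80, 87.2)])
res = predict_individual(rec, bundle, "logistic_regression")
print("frame          :", res.frame.months, "months")
print("three-class    :", res.three_class)
print("five-class     :", res.five_class)
print("probabilities  :", {k: round(v, 3) for k, v in res.probabilities.items()})
```

Output:

```
frame          : 3 months
three-class    : loss
five-class     : None
probabilities  : {'gain': 0.0, 'insufficient_loss': 0.007, 'loss': 0.992}
```

The last entry at day 80 selects the 3-month frame. Five-class
predictions are only reported for frames beyond four months, where they
become reliable, so this individual gets the three-class call only.

## Layout

| Module | Contents |
| --- | --- |
| `weighttraj.cohort_io` | CSV cohort reading/writing, exclusion criteria |
| `weighttraj.trajectory` | daily percent-change series, interpolation, extrapolation, frames |
| `weighttraj.dtw` | dynamic time warping (numba-accelerated, pure-python fallback) |
| `weighttraj.clustering` | consensus init, DTW-k-means, class schemes, cutoff refitting |
| `weighttraj.modeling` | feature encodings, six learners, stratified CV, per-frame bundles |
| `weighttraj.evaluation` | confusion matrices, per-class metrics, random baseline, validation |
| `weighttraj.synthetic` | archetype-based cohort generator with ground-truth labels |
| `weighttraj.cli` | `weighttraj simulate / cluster / train / predict / evaluate` |

Methodological details, parameter defaults and limitations are documented
in [`docs/methods.md`](docs/methods.md).
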
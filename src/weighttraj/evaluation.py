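"""Accuracy, per-class metrics, confusion matrices, and the random baseline.

Accuracy is the fraction of predictions matching the truth. Per-class
metrics are one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) and F1 = 2TP/(2TP+FP+FN). A metric whose denominator
is zero is reported as missing (NaN), never silently as zero. The random
baseline is the expected accuracy of drawing a class from the training
class distribution independently for each individual; it converges to
sum_c p_train(c) * p_truth(c).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .clustering import ClassScheme, collapse_classes

__all__ = ["ConfusionMatrix", "EvalReport", "evaluate", "random_baseline",
           "collapse_confusion", "validate_per_frame", "training_prevalence"]


@dataclass
class ConfusionMatrix:
    """k x k counts, rows = truth, columns = prediction, class order fixed."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape must match class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    confusion: ConfusionMatrix
    n: int
    random_baseline: float | None = None

    def macro(self, metric: str) -> float:
        """Unweighted mean of a per-class metric, ignoring undefined values."""
        vals = [v for v in getattr(self, metric).values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_json(self, path) -> None:
        def clean(d):
            return {k: (None if math.isnan(v) else v) for k, v in d.items()}

        obj = {
            "accuracy": self.accuracy,
            "n": self.n,
            "random_baseline": self.random_baseline,
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "precision": clean(self.precision),
            "f1": clean(self.f1),
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    def summary(self) -> str:
        lines = [f"n = {self.n}   accuracy = {self.accuracy:.3f}"]
        if self.random_baseline is not None:
            lines[0] += f"   random baseline = {self.random_baseline:.3f}"
        hdr = f"{'class':<20}{'sens':>8}{'spec':>8}{'prec':>8}{'F1':>8}"
        lines.append(hdr)
        for c in self.confusion.class_names:
            def fmt(d):
                v = d[c]
                return "   --" if math.isnan(v) else f"{v:8.3f}"
            lines.append(f"{c:<20}{fmt(self.sensitivity)}{fmt(self.specificity)}"
                         f"{fmt(self.precision)}{fmt(self.f1)}")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(predictions, truth, scheme: ClassScheme) -> EvalReport:
    """Compare predicted vs true class labels under a scheme."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and nonempty")
    names = scheme.class_names
    cm = _sk_confusion(truth, predictions, labels=list(names))
    n = int(cm.sum())
    sens, spec, prec, f1 = {}, {}, {}, {}
    for i, c in enumerate(names):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = _safe_div(tp, tp + fn)
        spec[c] = _safe_div(tn, tn + fp)
        prec[c] = _safe_div(tp, tp + fp)
        f1[c] = _safe_div(2 * tp, 2 * tp + fp + fn)
    return EvalReport(
        accuracy=float(np.trace(cm) / n),
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        confusion=ConfusionMatrix(cm, names), n=n,
    )


def collapse_confusion(cm: ConfusionMatrix, scheme: ClassScheme) -> ConfusionMatrix:
    """Collapse a five-class confusion matrix into a coarser scheme."""
    names = scheme.class_names
    out = np.zeros((len(names), len(names)), dtype=int)
    for i, ti in enumerate(cm.class_names):
        for j, tj in enumerate(cm.class_names):
            out[names.index(collapse_classes(ti, scheme)),
                names.index(collapse_classes(tj, scheme))] += cm.counts[i, j]
    return ConfusionMatrix(out, names)


def random_baseline(train_class_probs, truth, class_names,
                    n_rep: int = 10_000, seed: int = 0) -> float:
    """Mean accuracy of class draws from the training class distribution.

    Each replicate draws one class per individual (i.i.d. from
    ``train_class_probs``, aligned with ``class_names``) and scores accuracy
    against the truth; the mean over ``n_rep`` seeded replicates is returned.
    """
    probs = np.asarray(train_class_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError(f"class probabilities sum to {probs.sum()}, not 1")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    truth = np.asarray(truth)
    name_to_idx = {c: i for i, c in enumerate(class_names)}
    truth_idx = np.array([name_to_idx[t] for t in truth.tolist()])
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(probs), size=(n_rep, len(truth_idx)), p=probs)
    return float((draws == truth_idx[None, :]).mean())


def training_prevalence(bundle, scheme: ClassScheme) -> np.ndarray:
    """Training class frequencies under a scheme, from the bundle's labels."""
    if bundle.train_five_labels is None:
        raise ValueError("bundle carries no training labels")
    labels = [collapse_classes(l, scheme) for l in bundle.train_five_labels]
    counts = np.array([labels.count(c) for c in scheme.class_names], float)
    return counts / counts.sum()


def validate_per_frame(cohort, bundle, method: str = "logistic_regression",
                       scheme: ClassScheme | None = None,
                       n_rep: int = 10_000, seed: int = 0):
    """Frame-by-frame external validation of a trained bundle.

    Mirrors clinical use on an independent cohort: for each prediction time
    frame, only individuals passing the two eligibility rules are scored.
    Their observed series is interpolated, then extrapolated to the frame
    end using the average daily change from baseline to the last in-frame
    entry; the frame's trained model predicts the class. The truth is the
    DTW assignment of the individual's day-270 series to the training
    cluster means (collapsed for coarser schemes). Each report carries the
    random baseline computed from the training class distribution.

    Returns a dict mapping each TimeFrame to its EvalReport.
    """
    # imported here: evaluation is a leaf module for the metric functions,
    # but validation needs the modelling layer
    from .clustering import OUTCOME_DAY, assign_class_by_dtw
    from .modeling import build_features, check_eligibility
    from .trajectory import (
        extrapolate_to,
        percent_change_series,
        restrict_to_frame,
    )

    scheme = scheme or ClassScheme.three_class()
    probs = training_prevalence(bundle, scheme)
    cm = bundle.cluster_model
    results = {}
    for frame in bundle.frames:
        preds, truths = [], []
        for rec in cohort:
            ok, _ = check_eligibility(rec, frame)
            if not ok:
                continue
            series = percent_change_series(rec)
            s = restrict_to_frame(series, frame)
            tm = bundle.get(method, frame, scheme.n_classes)
            feats = build_features(s, rec, frame, tm.encoding, cm,
                                   bundle.frames).values
            preds.append(tm.predict_label(feats))
            five = assign_class_by_dtw(extrapolate_to(series, OUTCOME_DAY), cm)
            truths.append(collapse_classes(five, scheme))
        if not preds:
            continue
        report = evaluate(np.asarray(preds), np.asarray(truths), scheme)
        report.random_baseline = random_baseline(
            probs, truths, scheme.class_names, n_rep=n_rep, seed=seed
        )
        results[frame] = report
    return results
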
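"""Supervised prediction of 9-month weight-change class per time frame.

One predictor is trained per (method, time frame, class scheme). The general
model is y = f(x_t) + eps_t: y is the 9-month outcome (class label, or
percent change for regression-type methods), x_t the features available at
the end of the time frame, and eps_t an error term assumed independent of
x_t with mean zero and constant variance. Six learners are supported:
logistic regression, linear regression, Gaussian naive Bayes, support vector
classification/regression, and a multi-layer perceptron. Regression-type
methods predict a percent change that is mapped to a class via optimized
cutoffs.

Feature encodings (per frame ending at day T):
  * ``bmi_last``     — [BMI at baseline, percent change at day T]
  * ``bmi_history``  — [BMI at baseline, percent change at each grid frame
                        end <= T]
  * ``dtw_dists``    — DTW distance to each of the five cluster means
                        truncated to the frame
  * ``daily``        — [BMI at baseline, daily percent changes day 1..T]
                        (multi-layer-perceptron extra)

Cross-validation is fivefold and class-stratified: within each outcome
class, members are spread evenly over the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .clustering import (
    FIVE_TO_THREE,
    OUTCOME_DAY,
    ClassScheme,
    ClusterModel,
    assign_class_by_dtw,
    build_cluster_model,
    optimize_cutoffs,
)
from .cohort_io import ParticipantRecord
from .dtw import DtwConfig, dtw_distance
from .trajectory import (
    FRAME_GRID,
    DailySeries,
    TimeFrame,
    bmi,
    extrapolate_to,
    percent_change_series,
    restrict_to_frame,
)

__all__ = [
    "METHODS",
    "REGRESSION_METHODS",
    "TABLE_DEFAULT_ENCODING",
    "FeatureVector",
    "TrainedFrameModel",
    "ModelBundle",
    "TrainingConfig",
    "PredictionResult",
    "build_features",
    "stratified_folds",
    "train_bundle",
    "regression_to_class",
    "select_frame",
    "check_eligibility",
    "predict_individual",
    "EligibilityError",
    "TrainingError",
]

METHODS = (
    "logistic_regression",
    "linear_regression",
    "naive_bayes",
    "support_vector_classification",
    "support_vector_regression",
    "multilayer_perceptron",
)
REGRESSION_METHODS = frozenset({"linear_regression", "support_vector_regression"})

#: Default input encoding per method (best cross-validated choice).
TABLE_DEFAULT_ENCODING = {
    "logistic_regression": "dtw_dists",
    "linear_regression": "dtw_dists",
    "naive_bayes": "bmi_last",
    "support_vector_classification": "dtw_dists",
    "support_vector_regression": "bmi_last",
    "multilayer_perceptron": "bmi_last",
}
ENCODINGS = ("bmi_last", "bmi_history", "dtw_dists", "daily")


class EligibilityError(ValueError):
    def __init__(self, reasons: list[str]):
        super().__init__("; ".join(reasons))
        self.reasons = reasons


class TrainingError(RuntimeError):
    pass


@dataclass
class FeatureVector:
    values: np.ndarray
    encoding: str
    frame: TimeFrame


def build_features(
    series: DailySeries,
    rec: ParticipantRecord,
    frame: TimeFrame,
    encoding: str,
    model: ClusterModel,
    grid: tuple[TimeFrame, ...] = FRAME_GRID,
) -> FeatureVector:
    """Encode an individual's frame-restricted series as model input."""
    T = frame.end_day
    v = series.values
    if len(v) < T + 1:
        raise ValueError(
            f"series of length {len(v)} does not cover frame end day {T}; "
            "restrict/extrapolate to the frame first"
        )
    bmi0 = bmi(series.baseline_weight, rec.height_cm)
    if encoding == "bmi_last":
        values = np.array([bmi0, v[T]])
    elif encoding == "bmi_history":
        ends = [f.end_day for f in grid if f.end_day <= T]
        values = np.concatenate([[bmi0], v[ends]])
    elif encoding == "dtw_dists":
        means = model.truncated_means(T)
        values = np.array([dtw_distance(v[: T + 1], m, model.dtw_cfg)
                           for m in means])
    elif encoding == "daily":
        values = np.concatenate([[bmi0], v[1: T + 1]])
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return FeatureVector(values=values, encoding=encoding, frame=frame)


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment.

    Within each class, members are shuffled with the seeded generator;
    floor(n_c / n_folds) go to every fold and the remainder is dealt
    round-robin starting at fold 0. Every individual is assigned exactly
    once. A class smaller than ``n_folds`` is an error.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < n_folds:
            raise TrainingError(
                f"class {cls!r} has {len(idx)} members, fewer than "
                f"{n_folds} folds: stratification impossible"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), n_folds)
        sizes = [base + (1 if f < rem else 0) for f in range(n_folds)]
        pos = 0
        for f, sz in enumerate(sizes):
            folds[idx[pos: pos + sz]] = f
            pos += sz
    return folds


def regression_to_class(prediction: float, cutoffs, scheme: ClassScheme) -> str:
    """Map a predicted percent change to a class.

    Classes are ordered most-loss first; a prediction at or below a cutoff
    belongs to the class on the loss side (x <= cutoff -> lower class),
    matching the orientation used when the cutoffs were optimized.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) != scheme.n_classes - 1:
        raise ValueError("need n_classes - 1 cutoffs")
    idx = int(np.searchsorted(cutoffs, prediction, side="left"))
    return scheme.class_names[idx]


def select_frame(last_observed_day: int,
                 grid: tuple[TimeFrame, ...] = FRAME_GRID) -> TimeFrame:
    """The frame whose end is closest to the last observed day; ties go up."""
    if last_observed_day < 1:
        raise ValueError("need at least one day of follow-up")
    best = None
    best_gap = None
    for f in grid:
        gap = abs(f.end_day - last_observed_day)
        if best is None or gap < best_gap or (gap == best_gap
                                              and f.end_day > best.end_day):
            best, best_gap = f, gap
    return best


def check_eligibility(rec: ParticipantRecord,
                      frame: TimeFrame) -> tuple[bool, list[str]]:
    """The two rules gating whether a prediction is issued for a frame.

    (1) at least two weight entries within the frame; (2) the last entry in
    the frame no more than 30 days before the frame end.
    """
    in_frame = [e.day for e in rec.entries if e.day <= frame.end_day]
    reasons = []
    if len(in_frame) < 2:
        reasons.append(f"fewer than 2 entries within the first {frame.end_day} days")
    if not in_frame or max(in_frame) < frame.end_day - 30:
        reasons.append(
            f"last entry in frame not within 30 days of day {frame.end_day}"
        )
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    seed: int = 0
    n_folds: int = 5
    k: int = 5
    dtw: DtwConfig = field(default_factory=DtwConfig)
    frames: tuple[TimeFrame, ...] = FRAME_GRID
    consensus_variants: tuple[str, ...] = ("average", "complete", "ward")
    kmeans_max_iter: int = 50
    select_encoding: bool = False
    hyperparams: dict = field(default_factory=dict)


def _make_estimator(method: str, seed: int, overrides: dict | None = None):
    """Library-default-grade learner, standardized where scale matters."""
    overrides = overrides or {}
    if method == "logistic_regression":
        est = LogisticRegression(max_iter=2000, C=1.0, **overrides)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if method == "linear_regression":
        return Pipeline([("model", LinearRegression(**overrides))])
    if method == "naive_bayes":
        return Pipeline([("model", GaussianNB(**overrides))])
    if method == "support_vector_classification":
        est = SVC(kernel="rbf", **overrides)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if method == "support_vector_regression":
        est = SVR(kernel="rbf", **overrides)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if method == "multilayer_perceptron":
        # lbfgs converges reliably on the small, low-dimensional problems here
        params = dict(hidden_layer_sizes=(16,), solver="lbfgs",
                      max_iter=2000, random_state=seed)
        params.update(overrides)
        est = MLPClassifier(**params)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TrainedFrameModel:
    method: str
    frame: TimeFrame
    scheme: ClassScheme
    encoding: str
    estimator: object
    cutoffs: np.ndarray | None = None  # regression methods only

    @property
    def is_regression(self) -> bool:
        return self.method in REGRESSION_METHODS

    def predict_label(self, features: np.ndarray) -> str:
        X = np.atleast_2d(features)
        pred = self.estimator.predict(X)[0]
        if self.is_regression:
            return regression_to_class(float(pred), self.cutoffs, self.scheme)
        return str(pred)

    def predict_proba(self, features: np.ndarray) -> dict[str, float] | None:
        if self.is_regression or not hasattr(self.estimator, "predict_proba"):
            return None
        try:
            probs = self.estimator.predict_proba(np.atleast_2d(features))[0]
        except AttributeError:  # e.g. SVC without probability estimates
            return None
        classes = self.estimator.classes_
        return {str(c): float(p) for c, p in zip(classes, probs)}


@dataclass
class ModelBundle:
    """Trained predictors for every (method, frame, scheme) plus the outcome model."""

    cluster_model: ClusterModel
    models: dict
    cv_accuracy: dict
    config: TrainingConfig
    train_five_labels: list[str] | None = None  # outcome class per training id

    def get(self, method: str, frame: TimeFrame, n_classes: int) -> TrainedFrameModel:
        return self.models[(method, frame.end_day, n_classes)]

    @property
    def frames(self) -> tuple[TimeFrame, ...]:
        return self.config.frames

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        return joblib.load(path)


def _cohort_series(cohort, frames):
    """Per-individual full (day 270) and frame-restricted series."""
    full = []
    per_frame = {f.end_day: [] for f in frames}
    for rec in cohort:
        s = percent_change_series(rec)
        s270 = extrapolate_to(s, OUTCOME_DAY)
        full.append(s270)
        for f in frames:
            per_frame[f.end_day].append(restrict_to_frame(s, f))
    return full, per_frame


def _feature_matrix(cohort, series_list, frame, encoding, model, grid):
    rows = [build_features(s, rec, frame, encoding, model, grid).values
            for rec, s in zip(cohort, series_list)]
    return np.vstack(rows)


def _cv_accuracy(est_proto, X, y_class, y_reg, folds, scheme, is_reg, seed):
    accs = []
    for f in sorted(set(folds.tolist())):
        tr, te = folds != f, folds == f
        est = clone(est_proto)
        if is_reg:
            est.fit(X[tr], y_reg[tr])
            cutoffs = optimize_cutoffs(est.predict(X[tr]), y_class[tr], scheme)
            preds = [regression_to_class(p, cutoffs, scheme)
                     for p in est.predict(X[te])]
        else:
            est.fit(X[tr], y_class[tr])
            preds = est.predict(X[te])
        accs.append(float(np.mean(np.asarray(preds) == y_class[te])))
    return float(np.mean(accs))


def train_bundle(
    cohort: list[ParticipantRecord],
    methods: tuple[str, ...] = METHODS,
    schemes: tuple[ClassScheme, ...] | None = None,
    cfg: TrainingConfig | None = None,
    cluster_model: ClusterModel | None = None,
) -> ModelBundle:
    """Train all requested predictors on an exclusion-filtered cohort.

    The outcome definition (cluster model) is derived from the cohort unless
    one is supplied; every individual is labelled five-class by DTW
    assignment to the full 270-day means and three-class by collapsing.
    Regression targets are the day-270 percent change. CV accuracy is the
    mean fivefold class-stratified accuracy; regression methods additionally
    refit class cutoffs on the training folds' predictions.
    """
    cfg = cfg or TrainingConfig()
    schemes = schemes or (ClassScheme.three_class(), ClassScheme.five_class())
    full, per_frame = _cohort_series(cohort, cfg.frames)
    if cluster_model is None:
        cluster_model, five_labels, _, _ = build_cluster_model(
            full, cfg=cfg.dtw, k=cfg.k, variants=cfg.consensus_variants,
            max_iter=cfg.kmeans_max_iter,
        )
    else:
        five_labels = [assign_class_by_dtw(s, cluster_model) for s in full]
    labels_by_scheme = {
        s.n_classes: np.array([collapse_five(l, s) for l in five_labels])
        for s in schemes
    }
    for s in schemes:
        present = set(labels_by_scheme[s.n_classes].tolist())
        missing = [c for c in s.class_names if c not in present]
        if missing:
            raise TrainingError(f"no training members for class(es) {missing}")
    y_reg = np.array([s.values[OUTCOME_DAY] for s in full])

    feature_cache: dict[tuple[int, str], np.ndarray] = {}

    def features(frame, encoding):
        key = (frame.end_day, encoding)
        if key not in feature_cache:
            feature_cache[key] = _feature_matrix(
                cohort, per_frame[frame.end_day], frame, encoding,
                cluster_model, cfg.frames,
            )
        return feature_cache[key]

    folds_by_scheme = {
        s.n_classes: stratified_folds(labels_by_scheme[s.n_classes],
                                      cfg.n_folds, cfg.seed)
        for s in schemes
    }

    models: dict = {}
    cv_accuracy: dict = {}
    for method in methods:
        is_reg = method in REGRESSION_METHODS
        encoding = TABLE_DEFAULT_ENCODING[method]
        if cfg.select_encoding:
            encoding = _best_encoding(method, schemes, cfg, features,
                                      labels_by_scheme, y_reg, folds_by_scheme)
        proto = _make_estimator(method, cfg.seed,
                                cfg.hyperparams.get(method))
        for scheme in schemes:
            y_class = labels_by_scheme[scheme.n_classes]
            folds = folds_by_scheme[scheme.n_classes]
            for frame in cfg.frames:
                X = features(frame, encoding)
                acc = _cv_accuracy(proto, X, y_class, y_reg, folds, scheme,
                                   is_reg, cfg.seed)
                est = clone(proto)
                cutoffs = None
                if is_reg:
                    est.fit(X, y_reg)
                    cutoffs = optimize_cutoffs(est.predict(X), y_class, scheme)
                else:
                    est.fit(X, y_class)
                key = (method, frame.end_day, scheme.n_classes)
                models[key] = TrainedFrameModel(
                    method=method, frame=frame, scheme=scheme,
                    encoding=encoding, estimator=est, cutoffs=cutoffs,
                )
                cv_accuracy[key] = acc
    return ModelBundle(cluster_model=cluster_model, models=models,
                       cv_accuracy=cv_accuracy, config=cfg,
                       train_five_labels=list(five_labels))


def _best_encoding(method, schemes, cfg, features, labels_by_scheme, y_reg,
                   folds_by_scheme):
    """Encoding maximizing mean CV accuracy over frames and schemes."""
    candidates = ["bmi_last", "bmi_history", "dtw_dists"]
    if method == "multilayer_perceptron":
        candidates.append("daily")
    is_reg = method in REGRESSION_METHODS
    proto = _make_estimator(method, cfg.seed, cfg.hyperparams.get(method))
    best, best_acc = None, -1.0
    for enc in candidates:
        accs = []
        for scheme in schemes:
            for frame in cfg.frames:
                accs.append(_cv_accuracy(
                    proto, features(frame, enc),
                    labels_by_scheme[scheme.n_classes], y_reg,
                    folds_by_scheme[scheme.n_classes], scheme, is_reg,
                    cfg.seed,
                ))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best, best_acc = enc, mean_acc
    return best


def collapse_five(label: str, scheme: ClassScheme) -> str:
    """Collapse a five-class label into the given scheme."""
    if scheme.n_classes == 5:
        return label
    return FIVE_TO_THREE[label]


# ---------------------------------------------------------------------------
# Prediction service
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    id: str
    frame: TimeFrame
    three_class: str
    five_class: str | None  # only reported for frames beyond 4 months
    probabilities: dict[str, float] | None
    dtw_distances: dict[str, float]


#: Frames up to this end day report the three-class prediction only.
FIVE_CLASS_MIN_DAY = 120


def predict_individual(rec: ParticipantRecord, bundle: ModelBundle,
                       method: str = "logistic_regression") -> PredictionResult:
    """Predict the 9-month weight-change class for a partially observed individual.

    The frame closest to the individual's last entry is selected, the two
    eligibility rules are checked, the observed series is interpolated and
    extrapolated to the frame end, and the frame's trained model is applied.
    A five-class prediction is issued only when the selected frame extends
    beyond 4 months; the three-class prediction is always issued.
    """
    series = percent_change_series(rec)
    frame = select_frame(series.last_observed_day, bundle.frames)
    ok, reasons = check_eligibility(rec, frame)
    if not ok:
        raise EligibilityError(reasons)
    s = restrict_to_frame(series, frame)
    cm = bundle.cluster_model
    dists = {name: dtw_distance(s.values, m, cm.dtw_cfg)
             for name, m in zip(cm.class_names, cm.truncated_means(frame.end_day))}

    def run(n_classes):
        tm = bundle.get(method, frame, n_classes)
        feats = build_features(s, rec, frame, tm.encoding, cm,
                               bundle.frames).values
        return tm.predict_label(feats), tm.predict_proba(feats)

    three_label, three_proba = run(3)
    five_label = None
    proba = three_proba
    if (frame.end_day > FIVE_CLASS_MIN_DAY
            and (method, frame.end_day, 5) in bundle.models):
        five_label, five_proba = run(5)
        proba = five_proba if five_proba is not None else three_proba
    return PredictionResult(id=rec.id, frame=frame, three_class=three_label,
                            five_class=five_label, probabilities=proba,
                            dtw_distances=dists)
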
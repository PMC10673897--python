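"""Deriving the weight-change outcome classes by trajectory clustering.

Five classes (high/moderate weight loss, insufficient loss, low/high gain)
are defined data-driven in two steps: (1) several variants of agglomerative
hierarchical clustering on the pairwise DTW matrix, restricted by consensus
— only individuals placed in the same (label-matched) cluster by every
variant contribute to the initial centroids; (2) k-means refinement on the
whole cohort with DTW as the assignment distance and arithmetic per-day
means as centroids. A coarser three-class scheme (loss / insufficient loss /
gain) merges the two loss and the two gain classes.

Regression-type predictors output a 9-month percent change which is mapped
to a class through cutoff percentages chosen to minimize training
classification errors (ties resolved to the largest candidate cutoff).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .dtw import DtwConfig, dtw_distance, dtw_distance_matrix

__all__ = [
    "FIVE_CLASS_NAMES",
    "THREE_CLASS_NAMES",
    "FIVE_TO_THREE",
    "DEFAULT_FIVE_CLASS_CUTOFFS",
    "DEFAULT_THREE_CLASS_CUTOFFS",
    "ClassScheme",
    "ClusterModel",
    "KMeansResult",
    "consensus_from_labelings",
    "consensus_initial_centroids",
    "dtw_kmeans",
    "assign_class_by_dtw",
    "collapse_classes",
    "optimize_cutoffs",
    "build_cluster_model",
    "DegenerateConsensusError",
    "MissingClassError",
]

#: Five-class labels ordered from most weight loss to most weight gain.
FIVE_CLASS_NAMES = ("high_loss", "moderate_loss", "insufficient_loss",
                    "low_gain", "high_gain")
#: Three-class labels in the same order.
THREE_CLASS_NAMES = ("loss", "insufficient_loss", "gain")
FIVE_TO_THREE = {
    "high_loss": "loss",
    "moderate_loss": "loss",
    "insufficient_loss": "insufficient_loss",
    "low_gain": "gain",
    "high_gain": "gain",
}

# Published class boundaries (percent weight change at 9 months), shipped as
# fallbacks for use without a training cohort; retraining regenerates them.
DEFAULT_FIVE_CLASS_CUTOFFS = (-9.2, -2.4, -0.1, 2.2)
DEFAULT_THREE_CLASS_CUTOFFS = (-2.4, -0.1)

OUTCOME_DAY = 270  # 9 months at 30 days/month


class DegenerateConsensusError(RuntimeError):
    pass


class MissingClassError(ValueError):
    pass


@dataclass(frozen=True)
class ClassScheme:
    """A labelling scheme: the ordered class names and the 5->scheme mapping."""

    n_classes: int
    class_names: tuple[str, ...]
    mapping: tuple[tuple[str, str], ...]  # five-class label -> scheme label

    @classmethod
    def five_class(cls) -> "ClassScheme":
        return cls(5, FIVE_CLASS_NAMES,
                   tuple((c, c) for c in FIVE_CLASS_NAMES))

    @classmethod
    def three_class(cls) -> "ClassScheme":
        return cls(3, THREE_CLASS_NAMES, tuple(FIVE_TO_THREE.items()))

    def index(self, label: str) -> int:
        return self.class_names.index(label)


def collapse_classes(label: str, scheme: ClassScheme) -> str:
    """Map a five-class label into the scheme (identity for the five-class scheme)."""
    for src, dst in scheme.mapping:
        if src == label:
            return dst
    raise ValueError(f"unknown five-class label {label!r}")


@dataclass
class ClusterModel:
    """The trained outcome definition: five mean daily trajectories + cutoffs.

    ``means`` has shape (5, 271) — percent change per day for days 0..270,
    ordered from most loss to most gain to match ``class_names``. The cutoff
    vectors convert a 9-month percent change into a class (a value <= cutoff
    belongs to the class on the loss side of the boundary).
    """

    means: np.ndarray
    class_names: tuple[str, ...] = FIVE_CLASS_NAMES
    five_class_cutoffs: tuple[float, ...] = DEFAULT_FIVE_CLASS_CUTOFFS
    three_class_cutoffs: tuple[float, ...] = DEFAULT_THREE_CLASS_CUTOFFS
    dtw_cfg: DtwConfig = field(default_factory=DtwConfig)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim != 2 or self.means.shape[0] != len(self.class_names):
            raise ValueError("means must be one row per class")
        if not np.isfinite(self.means).all():
            raise ValueError("cluster means must be finite")
        for cuts in (self.five_class_cutoffs, self.three_class_cutoffs):
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError("cutoffs must be strictly increasing")

    def truncated_means(self, end_day: int | None) -> np.ndarray:
        if end_day is None:
            return self.means
        return self.means[:, : end_day + 1]

    def cutoffs_for(self, scheme: ClassScheme) -> tuple[float, ...]:
        return (self.three_class_cutoffs if scheme.n_classes == 3
                else self.five_class_cutoffs)

    # -- serialization --------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "class_names": list(self.class_names),
            "means": self.means.tolist(),
            "five_class_cutoffs": list(self.five_class_cutoffs),
            "three_class_cutoffs": list(self.three_class_cutoffs),
            "dtw": {"local_cost": self.dtw_cfg.local_cost,
                    "window": self.dtw_cfg.window,
                    "final_sqrt": self.dtw_cfg.final_sqrt},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(means=np.array(obj["means"]),
                   class_names=tuple(obj["class_names"]),
                   five_class_cutoffs=tuple(obj["five_class_cutoffs"]),
                   three_class_cutoffs=tuple(obj["three_class_cutoffs"]),
                   dtw_cfg=DtwConfig(**obj["dtw"]))


def _series_matrix(cohort_series) -> np.ndarray:
    vecs = [np.asarray(getattr(s, "values", s), dtype=float) for s in cohort_series]
    lengths = {len(v) for v in vecs}
    if len(lengths) != 1:
        raise ValueError("all series must share the daily grid (equal length)")
    return np.vstack(vecs)


def _match_labels(ref: np.ndarray, other: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``other`` to maximize overlap with ``ref`` (Hungarian assignment)."""
    contingency = np.zeros((k, k), dtype=int)
    for a, b in zip(ref, other):
        contingency[a, b] += 1
    rows, cols = linear_sum_assignment(-contingency)
    remap = np.empty(k, dtype=int)
    remap[cols] = rows
    return remap[other]


def consensus_from_labelings(X: np.ndarray, labelings, k: int):
    """Consensus bookkeeping given the per-variant cluster labelings.

    Labelings are matched to the first one by maximal-overlap (Hungarian)
    assignment; an individual is consensual iff all matched labels agree.
    Returns ``(centroids, consensus_fraction, ref_labels)`` where centroid c
    is the per-day mean over consensual members of cluster c.
    """
    ref = np.asarray(labelings[0])
    matched = [ref] + [_match_labels(ref, np.asarray(lab), k)
                       for lab in labelings[1:]]
    agree = np.all(np.vstack(matched) == ref, axis=0)
    centroids = np.empty((k, X.shape[1]))
    for c in range(k):
        members = agree & (ref == c)
        if not members.any():
            raise DegenerateConsensusError(
                f"consensus cluster {c} has no members; "
                f"consensus fraction {agree.mean():.3f}"
            )
        centroids[c] = X[members].mean(axis=0)
    return centroids, float(agree.mean()), ref


def consensus_initial_centroids(
    cohort_series,
    k: int = 5,
    variants: tuple[str, ...] = ("average", "complete", "ward"),
    cfg: DtwConfig | None = None,
    distance_matrix: np.ndarray | None = None,
):
    """Initial centroids from the consensus of hierarchical clustering variants.

    Each linkage variant produces a k-clustering of the DTW distance matrix;
    clusterings are label-matched to the first variant by maximal overlap. An
    individual is consensual iff all variants then agree on its cluster, and
    each initial centroid is the arithmetic per-day mean over the consensual
    members of that cluster.

    Returns ``(centroids, consensus_fraction, ref_labels)`` where
    ``ref_labels`` are the matched cluster indices of the first variant.
    """
    cfg = cfg or DtwConfig()
    if k < 2 or len(variants) < 2:
        raise ValueError("need k >= 2 and at least 2 clustering variants")
    X = _series_matrix(cohort_series)
    D = distance_matrix if distance_matrix is not None else dtw_distance_matrix(X, cfg)
    condensed = squareform(D, checks=False)
    labelings = []
    for method in variants:
        Z = linkage(condensed, method=method)
        labelings.append(fcluster(Z, t=k, criterion="maxclust") - 1)
    return consensus_from_labelings(X, labelings, k)


@dataclass
class KMeansResult:
    centroids: np.ndarray
    labels: np.ndarray
    objective: list[float]  # sum of member-to-centroid DTW distances per iteration
    n_iter: int


def dtw_kmeans(
    cohort_series,
    init_centroids: np.ndarray,
    cfg: DtwConfig | None = None,
    max_iter: int = 50,
    tol: float = 0.0,
) -> KMeansResult:
    """k-means with DTW assignment and arithmetic per-day mean centroids.

    Iterates assignment (nearest centroid by DTW, ties to the lowest cluster
    index via ``argmin``) and centroid update (per-day mean of assigned
    series) until assignments stabilize, the largest centroid movement drops
    to ``tol`` or below, or ``max_iter`` is reached. A cluster left empty
    keeps its previous centroid.
    """
    cfg = cfg or DtwConfig()
    X = _series_matrix(cohort_series)
    centroids = np.asarray(init_centroids, dtype=float).copy()
    if centroids.shape[1] != X.shape[1]:
        raise ValueError("centroids must share the series grid length")
    k = centroids.shape[0]
    labels = np.full(X.shape[0], -1, dtype=int)
    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dists = np.empty((X.shape[0], k))
        for c in range(k):
            for i in range(X.shape[0]):
                dists[i, c] = dtw_distance(X[i], centroids[c], cfg)
        new_labels = dists.argmin(axis=1)
        objective.append(float(dists[np.arange(len(X)), new_labels].sum()))
        converged = bool((new_labels == labels).all())
        labels = new_labels
        shift = 0.0
        for c in range(k):
            members = labels == c
            if not members.any():
                warnings.warn(f"cluster {c} empty at iteration {n_iter}; "
                              "keeping previous centroid")
                continue
            new_c = X[members].mean(axis=0)
            shift = max(shift, float(np.abs(new_c - centroids[c]).max()))
            centroids[c] = new_c
        if converged or shift <= tol:
            break
    return KMeansResult(centroids=centroids, labels=labels,
                        objective=objective, n_iter=n_iter)


def assign_class_by_dtw(series, model: ClusterModel,
                        frame_end: int | None = None) -> str:
    """Assign a series to the class whose mean trajectory is DTW-nearest.

    With ``frame_end`` given, the cluster means are truncated to days
    0..frame_end before comparison (a short observed series compared against
    full 270-day means would be dominated by the length mismatch). Ties go
    to the lower class index.
    """
    means = model.truncated_means(frame_end)
    dists = [dtw_distance(series, m, model.dtw_cfg) for m in means]
    return model.class_names[int(np.argmin(dists))]


def optimize_cutoffs(observed_9mo, labels, scheme: ClassScheme) -> np.ndarray:
    """Class boundaries on the 9-month percent change minimizing training errors.

    For each adjacent class pair (classes ordered most-loss first) the
    boundary is chosen among the observed values of that pair's members: a
    cutoff v assigns x to the lower (more-loss) class iff x <= v. Among
    error-minimizing candidates the largest value is returned; boundaries are
    solved independently per pair.
    """
    observed = np.asarray(observed_9mo, dtype=float)
    labels = np.asarray(labels)
    if observed.shape != labels.shape:
        raise ValueError("observed values and labels must align")
    cutoffs = []
    for lo_name, hi_name in zip(scheme.class_names, scheme.class_names[1:]):
        lo = observed[labels == lo_name]
        hi = observed[labels == hi_name]
        if lo.size == 0 or hi.size == 0:
            empty = lo_name if lo.size == 0 else hi_name
            raise MissingClassError(f"class {empty!r} has no members")
        candidates = np.unique(np.concatenate([lo, hi]))
        # errors(v) = members of lo above v + members of hi at or below v
        errors = [(lo > v).sum() + (hi <= v).sum() for v in candidates]
        best = min(errors)
        cutoffs.append(float(candidates[np.nonzero(np.array(errors) == best)[0][-1]]))
    return np.array(cutoffs)


def build_cluster_model(
    cohort_series,
    cfg: DtwConfig | None = None,
    k: int = 5,
    variants: tuple[str, ...] = ("average", "complete", "ward"),
    max_iter: int = 50,
    refit_cutoffs: bool = True,
):
    """Full outcome-definition pipeline on day-0..270 series.

    Consensus hierarchical clustering seeds DTW-k-means; the refined
    centroids are ordered by their day-270 value (most loss first) and named
    after the five classes. Cutoffs are refit from the observed 9-month
    percent changes under the resulting labels (unless ``refit_cutoffs`` is
    False, in which case the shipped defaults remain).

    Returns ``(model, labels, consensus_fraction, kmeans_result)`` with
    ``labels`` the five-class label per input series.
    """
    cfg = cfg or DtwConfig()
    X = _series_matrix(cohort_series)
    if X.shape[1] != OUTCOME_DAY + 1:
        raise ValueError(f"series must span days 0..{OUTCOME_DAY}")
    D = dtw_distance_matrix(X, cfg)
    init, frac, _ = consensus_initial_centroids(
        X, k=k, variants=variants, cfg=cfg, distance_matrix=D
    )
    km = dtw_kmeans(X, init, cfg, max_iter=max_iter)
    order = np.argsort(km.centroids[:, -1])  # most loss -> most gain
    means = km.centroids[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    km.labels = relabel[km.labels]
    km.centroids = means
    names = FIVE_CLASS_NAMES if k == 5 else tuple(f"class_{i}" for i in range(k))
    labels = [names[i] for i in km.labels]
    model = ClusterModel(means=means, class_names=names, dtw_cfg=cfg)
    if refit_cutoffs and k == 5:
        observed = X[:, OUTCOME_DAY]
        five = optimize_cutoffs(observed, labels, ClassScheme.five_class())
        three_labels = [FIVE_TO_THREE[l] for l in labels]
        three = optimize_cutoffs(observed, three_labels, ClassScheme.three_class())
        model = ClusterModel(means=means, class_names=names,
                             five_class_cutoffs=tuple(five),
                             three_class_cutoffs=tuple(three), dtw_cfg=cfg)
    return model, labels, frac, km
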
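"""Synthetic cohorts of self-reported weight trajectories with known classes.

The real coaching and validation cohorts behind this framework cannot be
redistributed, so every stage of the pipeline is exercised on generated
data. Each individual follows one of five archetype trajectories — an
exponential-plateau percent-change curve a*(1 - exp(-d/tau)) whose terminal
(day 270) value sits inside the corresponding class band — sampled at
irregular days with i.i.d. Gaussian measurement noise in percent space.

Two sampling regimes are provided: a dense training-style regime (entry
counts centred near the mid-thirties over a 270-day span) and a sparse
validation-style regime (median around 16 entries, a configurable fraction
of individuals truncated before day 270).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import FIVE_CLASS_NAMES
from .cohort_io import ParticipantRecord, WeightEntry

__all__ = [
    "ArchetypeSpec",
    "SimConfig",
    "default_archetypes",
    "generate_cohort",
    "class_prevalence",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One class's mean trajectory: percent change a*(1 - exp(-d/tau)).

    ``terminal_value`` is the percent change reached at day 270; the
    amplitude ``a`` is solved from it so the curve lands on the class band.
    """

    name: str
    terminal_value: float
    tau_days: float = 70.0

    @property
    def amplitude(self) -> float:
        return self.terminal_value / (1.0 - math.exp(-270.0 / self.tau_days))

    def curve(self, days) -> np.ndarray:
        d = np.asarray(days, dtype=float)
        return self.amplitude * (1.0 - np.exp(-d / self.tau_days))


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """Archetypes whose day-270 values fall inside the five class bands.

    High loss beyond -10%, moderate loss in the 5-10% band, insufficient
    loss near zero, and low/high gain at roughly +1.5% and +5%. Loss curves
    plateau faster (smaller tau) than gain curves, mirroring the typical
    shape of intervention trajectories: rapid initial loss, then a plateau.
    """
    return (
        ArchetypeSpec("high_loss", -12.0, tau_days=70.0),
        ArchetypeSpec("moderate_loss", -7.0, tau_days=70.0),
        ArchetypeSpec("insufficient_loss", -1.5, tau_days=50.0),
        ArchetypeSpec("low_gain", 1.5, tau_days=120.0),
        ArchetypeSpec("high_gain", 5.0, tau_days=120.0),
    )


@dataclass
class SimConfig:
    """Generator settings.

    ``entry_count_range`` bounds the uniform draw of entries per individual;
    the training-style default (10, 62) centres near the mid-thirties. With
    ``sparse_mode`` the follow-up of ``truncate_fraction`` of individuals
    ends at a uniform day in [min_truncation_day, span_days] — the
    validation-style regime; pair it with a lower ``entry_count_range``
    (e.g. (3, 30)) to emulate sparse self-reporting. ``noise_sd`` is the
    per-observation measurement noise in percent of baseline weight.
    """

    seed: int
    n_per_class: tuple[int, ...] = (60, 60, 60, 60, 60)
    noise_sd: float = 0.5
    entry_count_range: tuple[int, int] = (10, 62)
    span_days: int = 270
    sparse_mode: bool = False
    truncate_fraction: float = 0.5
    min_truncation_day: int = 60
    baseline_weight_range: tuple[float, float] = (80.0, 130.0)
    height_range: tuple[float, float] = (155.0, 195.0)
    noise_walk: bool = False  # random-walk noise instead of i.i.d.
    inject_violations: int = 0  # stress: individuals given a >1.5 kg/day jump
    max_daily_change_kg: float = 1.5  # guard honoured by the repair pass

    @classmethod
    def validation_style(cls, seed: int, **kw) -> "SimConfig":
        defaults = dict(sparse_mode=True, entry_count_range=(3, 30))
        defaults.update(kw)
        return cls(seed=seed, **defaults)


def _draw_entry_days(rng, n_entries: int, last_day: int) -> np.ndarray:
    """Day 0 plus n-1 distinct later days up to last_day, ending at last_day."""
    n_entries = min(n_entries, last_day + 1)
    later = rng.choice(np.arange(1, last_day + 1), size=n_entries - 1,
                       replace=False)
    later = np.sort(later)
    later[-1] = last_day  # anchor the follow-up end
    return np.concatenate([[0], np.unique(later)])


def _repair_rates(days, weights, limit_kg: float) -> np.ndarray:
    """Damp measurement noise where consecutive entries would exceed the
    plausible-change limit; the underlying mean curves never do, so pulling
    an offending entry toward its neighbour always terminates."""
    weights = weights.copy()
    for _ in range(200):
        rates = np.abs(np.diff(weights)) / np.diff(days)
        bad = np.nonzero(rates > 0.95 * limit_kg)[0]
        if bad.size == 0:
            break
        i = bad[0] + 1
        weights[i] = 0.5 * (weights[i] + weights[i - 1])
    return weights


def generate_cohort(
    cfg: SimConfig,
    archetypes: tuple[ArchetypeSpec, ...] | None = None,
) -> tuple[list[ParticipantRecord], dict[str, str]]:
    """Generate a cohort plus generator-truth class labels.

    Per individual: archetype per ``n_per_class``, baseline weight and
    height uniform in their ranges, irregular entry days, and observed
    weight ``baseline * (1 + (curve(d) + eps_d)/100)`` with
    ``eps_d ~ N(0, noise_sd)`` (or a random walk of that increment when
    ``noise_walk``). A repair pass keeps day-to-day changes below the
    1.5 kg/day plausibility limit unless violations are injected on purpose.
    """
    archetypes = archetypes or default_archetypes()
    if len(cfg.n_per_class) != len(archetypes):
        raise ValueError("n_per_class must match the number of archetypes")
    rng = np.random.default_rng(cfg.seed)
    records: list[ParticipantRecord] = []
    truth: dict[str, str] = {}
    idx = 0
    for arch, n in zip(archetypes, cfg.n_per_class):
        for _ in range(n):
            idx += 1
            pid = f"S{idx:04d}"
            baseline = rng.uniform(*cfg.baseline_weight_range)
            height = rng.uniform(*cfg.height_range)
            n_entries = int(rng.integers(cfg.entry_count_range[0],
                                         cfg.entry_count_range[1] + 1))
            last_day = cfg.span_days
            if cfg.sparse_mode and rng.random() < cfg.truncate_fraction:
                last_day = int(rng.integers(cfg.min_truncation_day,
                                            cfg.span_days + 1))
            days = _draw_entry_days(rng, n_entries, last_day)
            eps = rng.normal(0.0, cfg.noise_sd, size=len(days))
            if cfg.noise_walk:
                eps = np.cumsum(eps)
            eps[0] = 0.0  # baseline entry defines day 0 exactly
            pct = arch.curve(days) + eps
            weights = baseline * (1.0 + pct / 100.0)
            weights = _repair_rates(days, weights, cfg.max_daily_change_kg)
            entries = [WeightEntry(int(d), float(w))
                       for d, w in zip(days, weights)]
            records.append(ParticipantRecord(id=pid, height_cm=float(height),
                                             entries=entries))
            truth[pid] = arch.name
    if cfg.inject_violations:
        for rec in records[: cfg.inject_violations]:
            if len(rec.entries) >= 2:
                e0, e1 = rec.entries[0], rec.entries[1]
                jump = cfg.max_daily_change_kg * (e1.day - e0.day) + 1.0
                rec.entries[1] = WeightEntry(e1.day, e0.weight + jump)
    return records, truth


def class_prevalence(truth, class_names=FIVE_CLASS_NAMES) -> np.ndarray:
    """Empirical class frequencies aligned with ``class_names``; sums to 1."""
    labels = list(truth.values()) if isinstance(truth, dict) else list(truth)
    if not labels:
        raise ValueError("need at least one label")
    counts = np.array([labels.count(c) for c in class_names], dtype=float)
    if counts.sum() != len(labels):
        unknown = sorted(set(labels) - set(class_names))
        raise ValueError(f"labels outside class_names: {unknown}")
    return counts / counts.sum()


def write_truth(truth: dict[str, str], path) -> None:
    pd.DataFrame(sorted(truth.items()), columns=["id", "class"]).to_csv(
        path, index=False
    )


def read_truth(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["id"].astype(str), df["class"]))
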
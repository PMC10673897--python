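"""Daily percent-weight-change series: interpolation, extrapolation, time frames.

Raw weight logs are irregularly sampled. All downstream machinery (clustering,
feature construction, class assignment) operates on a dense integer daily grid
of *percent* weight change relative to the baseline entry, with day 0 defined
as the day of the first weight entry. Values are kept on the percent scale
(-5.0 means a 5% loss), matching the scale on which class cutoffs are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import ParticipantRecord

__all__ = [
    "DailySeries",
    "TimeFrame",
    "FRAME_GRID",
    "percent_change_series",
    "extrapolate_to",
    "restrict_to_frame",
    "bmi",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a record has too few entries to form a series."""


@dataclass
class DailySeries:
    """Percent weight change on a dense daily grid starting at day 0.

    Attributes
    ----------
    values
        ``values[d]`` is the percent weight change at day ``d`` relative to
        baseline; ``values[0] == 0.0``.
    last_observed_day
        Last day backed by an actual weight entry; days beyond it (if any)
        are extrapolated.
    baseline_weight
        Weight in kg at day 0.
    """

    values: np.ndarray
    last_observed_day: int
    baseline_weight: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("series must be a nonempty 1-d vector")
        if not np.isfinite(self.values).all():
            raise ValueError("series contains non-finite values")

    @property
    def end_day(self) -> int:
        return len(self.values) - 1


@dataclass(frozen=True)
class TimeFrame:
    """A prediction window [day 0, end_day], labelled in 30-day months."""

    months: float
    end_day: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "end_day", int(round(self.months * 30)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.months:g}mo"


#: The nine prediction time frames: 0.5 through 8 months at 30 days/month.
FRAME_GRID: tuple[TimeFrame, ...] = tuple(
    TimeFrame(m) for m in (0.5, 1, 2, 3, 4, 5, 6, 7, 8)
)


def percent_change_series(rec: ParticipantRecord) -> DailySeries:
    """Convert a raw weight log to a daily percent-change series.

    The baseline weight is the entry at day 0 (the first entry). Entry days
    are mapped to ``100 * (w(d) - w(0)) / w(0)`` and days between entries are
    linearly interpolated. The series ends at the last entry day.

    Raises
    ------
    InsufficientDataError
        If the record has fewer than two entries.
    """
    if len(rec.entries) < 2:
        raise InsufficientDataError(
            f"participant {rec.id!r}: need at least 2 weight entries, "
            f"got {len(rec.entries)}"
        )
    days = np.array([e.day for e in rec.entries], dtype=float)
    weights = np.array([e.weight for e in rec.entries], dtype=float)
    days -= days[0]  # day 0 = first entry
    baseline = weights[0]
    pct = 100.0 * (weights - baseline) / baseline
    last_day = int(days[-1])
    grid = np.arange(last_day + 1, dtype=float)
    values = np.interp(grid, days, pct)
    return DailySeries(values=values, last_observed_day=last_day,
                       baseline_weight=float(baseline))


def extrapolate_to(series: DailySeries, end_day: int) -> DailySeries:
    """Extend (or truncate) a series to ``end_day``.

    Beyond the last observed day the series continues along the straight line
    through the origin and the last observed point, i.e. using the average
    percent change per day between baseline and the last observation:
    ``values[d] = d * values[last] / last``. If the series already reaches
    ``end_day`` it is truncated with no extrapolation.
    """
    last = series.last_observed_day
    if end_day <= last:
        return DailySeries(values=series.values[: end_day + 1].copy(),
                           last_observed_day=min(last, end_day),
                           baseline_weight=series.baseline_weight)
    if last == 0:
        raise ValueError(
            "cannot extrapolate from a single day-0 observation: "
            "average daily slope is undefined"
        )
    slope = series.values[last] / last
    extra_days = np.arange(last + 1, end_day + 1, dtype=float)
    values = np.concatenate([series.values[: last + 1], extra_days * slope])
    return DailySeries(values=values, last_observed_day=last,
                       baseline_weight=series.baseline_weight)


def restrict_to_frame(series: DailySeries, frame: TimeFrame) -> DailySeries:
    """Limit a series to a prediction time frame, extrapolating if needed."""
    return extrapolate_to(series, frame.end_day)


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h = height_cm / 100.0
    return weight_kg / (h * h)
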
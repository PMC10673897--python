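"""Reading weight-log cohorts and applying participant exclusion criteria.

A cohort is a CSV of self-reported weight entries (``id``, ``day`` or ISO
``date``, ``weight_kg``) plus a height table (``id``, ``height_cm``).
Exclusion criteria screen out records that cannot support 9-month trajectory
modelling: too few entries, implausible day-to-day weight change, follow-up
shorter than the outcome horizon, implausible height, and (for the training
setting) known weight-loss medication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightEntry",
    "ParticipantRecord",
    "ExclusionConfig",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "write_exclusion_log",
    "CohortFormatError",
]


class CohortFormatError(ValueError):
    """Malformed cohort file (missing columns, unparseable values)."""


@dataclass(frozen=True)
class WeightEntry:
    """One self-reported weight measurement.

    ``day`` counts days since the participant's first entry (day 0);
    ``weight`` is in kg.
    """

    day: int
    weight: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class ParticipantRecord:
    """One individual's weight log plus baseline height."""

    id: str
    height_cm: float
    entries: list[WeightEntry] = field(default_factory=list)
    medication_flag: bool = False

    def __post_init__(self) -> None:
        days = [e.day for e in self.entries]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"participant {self.id!r}: entry days must be strictly increasing"
            )

    @property
    def span_days(self) -> int:
        """Days between first and last entry (0 if fewer than 2 entries)."""
        if len(self.entries) < 2:
            return 0
        return self.entries[-1].day - self.entries[0].day


@dataclass
class ExclusionConfig:
    """Thresholds for the participant exclusion criteria.

    Defaults correspond to the training setting: a record is dropped if it
    shows a weight change of more than 1.5 kg/day between consecutive
    entries, has fewer than 2 entries, spans less than 270 days, reports a
    height of 100 cm or less (inclusive bound: exactly 100 cm is excluded),
    or carries a known weight-loss-medication flag. ``require_entry_within_days``
    additionally demands at least one entry within the first N days, the
    criterion used for external validation cohorts; for records that already
    pass the other defaults it is never the binding constraint.
    """

    max_daily_change_kg: float = 1.5
    min_entries: int = 2
    min_span_days: int = 270
    min_height_cm: float = 100.0
    exclude_medication: bool = True
    require_entry_within_days: int | None = 270

    @classmethod
    def validation_default(cls) -> "ExclusionConfig":
        """Validation-cohort setting: medication data unavailable, span rule kept."""
        return cls(exclude_medication=False, require_entry_within_days=270)


def read_cohort(path, height_table) -> list[ParticipantRecord]:
    """Read a weight-log CSV and a height table into participant records.

    The weight log needs columns ``id``, ``weight_kg`` and either ``day``
    (integer offsets) or ``date`` (ISO 8601, converted to offsets from each
    participant's first entry). Duplicate (id, day) rows are collapsed to
    their mean weight. The height table maps ``id`` to ``height_cm``; an
    optional ``medication`` column (0/1) sets the medication flag.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or "weight_kg" not in df.columns:
        raise CohortFormatError(
            f"weight log must have columns 'id' and 'weight_kg'; got {list(df.columns)}"
        )
    if "day" in df.columns:
        day = pd.to_numeric(df["day"], errors="coerce")
        if day.isna().any():
            bad = df.index[day.isna()][0]
            raise CohortFormatError(f"non-numeric day at row {bad}")
        df = df.assign(day=day.astype(int))
    elif "date" in df.columns:
        dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
        if dates.isna().any():
            bad = df.index[dates.isna()][0]
            raise CohortFormatError(f"unparseable ISO date at row {bad}")
        offsets = dates - dates.groupby(df["id"]).transform("min")
        df = df.assign(day=offsets.dt.days.astype(int))
    else:
        raise CohortFormatError("weight log must have a 'day' or 'date' column")

    weight = pd.to_numeric(df["weight_kg"], errors="coerce")
    if weight.isna().any():
        bad = df.index[weight.isna()][0]
        raise CohortFormatError(f"non-numeric weight_kg at row {bad}")
    df = df.assign(weight_kg=weight)

    hts = pd.read_csv(height_table)
    if "id" not in hts.columns or "height_cm" not in hts.columns:
        raise CohortFormatError("height table must have columns 'id' and 'height_cm'")
    hts = hts.set_index(hts["id"].astype(str))
    missing = sorted(set(df["id"].astype(str)) - set(hts.index))
    if missing:
        raise CohortFormatError(f"ids missing from height table: {missing}")

    records = []
    for pid, grp in df.groupby(df["id"].astype(str), sort=True):
        # collapse duplicate days to the mean weight, then normalize day 0
        collapsed = grp.groupby("day", sort=True)["weight_kg"].mean()
        days = collapsed.index.to_numpy() - collapsed.index.min()
        entries = [WeightEntry(int(d), float(w)) for d, w in zip(days, collapsed)]
        row = hts.loc[pid]
        med = bool(row["medication"]) if "medication" in hts.columns else False
        records.append(ParticipantRecord(id=pid, height_cm=float(row["height_cm"]),
                                         entries=entries, medication_flag=med))
    return records


def write_cohort(cohort: list[ParticipantRecord], path, height_table) -> None:
    """Write records back to the weight-log / height-table CSV dialect."""
    rows = [(r.id, e.day, e.weight) for r in cohort for e in r.entries]
    pd.DataFrame(rows, columns=["id", "day", "weight_kg"]).to_csv(path, index=False)
    hrows = [(r.id, r.height_cm, int(r.medication_flag)) for r in cohort]
    pd.DataFrame(hrows, columns=["id", "height_cm", "medication"]).to_csv(
        height_table, index=False
    )


def _triggered_criteria(rec: ParticipantRecord, cfg: ExclusionConfig) -> list[str]:
    reasons = []
    if cfg.exclude_medication and rec.medication_flag:
        reasons.append("medication")
    if len(rec.entries) < cfg.min_entries:
        reasons.append("min_entries")
    days = np.array([e.day for e in rec.entries], dtype=float)
    weights = np.array([e.weight for e in rec.entries], dtype=float)
    if len(rec.entries) >= 2:
        rates = np.abs(np.diff(weights)) / np.diff(days)
        if (rates > cfg.max_daily_change_kg).any():
            reasons.append("max_daily_change")
    if rec.span_days < cfg.min_span_days:
        reasons.append("min_span")
    if rec.height_cm <= cfg.min_height_cm:
        reasons.append("min_height")
    if cfg.require_entry_within_days is not None:
        if not rec.entries or rec.entries[0].day > cfg.require_entry_within_days:
            reasons.append("entry_within_days")
    return reasons


def apply_exclusions(
    cohort: list[ParticipantRecord], cfg: ExclusionConfig | None = None
) -> tuple[list[ParticipantRecord], dict[str, list[str]]]:
    """Partition a cohort into kept records and an exclusion log.

    A record is kept iff it triggers no enabled criterion. The log maps each
    excluded id to the full list of criteria it triggered (a record can
    trigger several). Kept and excluded sets partition the input.
    """
    cfg = cfg or ExclusionConfig()
    kept, log = [], {}
    for rec in cohort:
        reasons = _triggered_criteria(rec, cfg)
        if reasons:
            log[rec.id] = reasons
        else:
            kept.append(rec)
    return kept, log


def write_exclusion_log(log: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcriteria\n")
        for pid in sorted(log):
            fh.write(f"{pid}\t{','.join(log[pid])}\n")
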
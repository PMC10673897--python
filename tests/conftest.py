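import numpy as np
import pytest

from weighttraj.cohort_io import ParticipantRecord, WeightEntry
from weighttraj.clustering import OUTCOME_DAY, build_cluster_model
from weighttraj.synthetic import SimConfig, generate_cohort
from weighttraj.trajectory import extrapolate_to, percent_change_series


def make_record(day_weight_pairs, pid="p1", height=170.0, medication=False):
    entries = [WeightEntry(int(d), float(w)) for d, w in day_weight_pairs]
    return ParticipantRecord(id=pid, height_cm=height, entries=entries,
                             medication_flag=medication)


def cohort_series(cohort):
    return [extrapolate_to(percent_change_series(r), OUTCOME_DAY)
            for r in cohort]


@pytest.fixture(scope="session")
def small_cohort():
    """50-per-class training-style cohort at the default noise level."""
    cfg = SimConfig(seed=11, n_per_class=(50,) * 5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cluster_model(small_cohort):
    cohort, truth = small_cohort
    series = cohort_series(cohort)
    model, labels, frac, km = build_cluster_model(series)
    return {"model": model, "labels": labels, "consensus_fraction": frac,
            "kmeans": km, "series": series, "cohort": cohort, "truth": truth}
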
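"""Feature encodings, stratified CV, frame selection, eligibility, prediction."""

import numpy as np
import pytest

from weighttraj.clustering import ClassScheme, ClusterModel
from weighttraj.modeling import (
    EligibilityError,
    TrainingError,
    build_features,
    check_eligibility,
    predict_individual,
    regression_to_class,
    select_frame,
    stratified_folds,
    train_bundle,
)
from weighttraj.synthetic import default_archetypes
from weighttraj.trajectory import FRAME_GRID, TimeFrame, bmi, restrict_to_frame
from weighttraj.trajectory import percent_change_series

from conftest import make_record


def toy_model():
    days = np.arange(271)
    return ClusterModel(np.vstack([a.curve(days) for a in default_archetypes()]))


def flat_series(frame):
    rec = make_record([(0, 100.0), (270, 100.0)])
    return restrict_to_frame(percent_change_series(rec), frame), rec


class TestBuildFeatures:
    def test_bmi_last_on_flat_series(self):
        frame = TimeFrame(3)
        s, rec = flat_series(frame)
        fv = build_features(s, rec, frame, "bmi_last", toy_model())
        np.testing.assert_allclose(fv.values,
                                   [bmi(100, rec.height_cm), 0.0])

    def test_bmi_history_length_counts_grid_ends(self):
        # grid ends <= 60 are {15, 30, 60}: BMI plus three values
        frame = TimeFrame(2)
        s, rec = flat_series(frame)
        fv = build_features(s, rec, frame, "bmi_history", toy_model())
        assert len(fv.values) == 4

    @pytest.mark.parametrize("months, expect_len", [
        (0.5, 2), (1, 3), (4, 6), (8, 10),
    ])
    def test_bmi_history_lengths_across_grid(self, months, expect_len):
        frame = TimeFrame(months)
        s, rec = flat_series(frame)
        fv = build_features(s, rec, frame, "bmi_history", toy_model())
        assert len(fv.values) == expect_len

    def test_dtw_dists_zero_at_own_cluster(self):
        model = toy_model()
        frame = TimeFrame(8)
        rec = make_record([(0, 100.0), (270, 95.0)])
        days = np.arange(frame.end_day + 1)
        s = restrict_to_frame(percent_change_series(rec), frame)
        s.values = default_archetypes()[1].curve(days)
        fv = build_features(s, rec, frame, "dtw_dists", model)
        assert len(fv.values) == 5
        assert fv.values[1] == pytest.approx(0.0, abs=1e-10)
        assert (np.delete(fv.values, 1) > 0).all()

    def test_daily_length_is_one_plus_frame_days(self):
        frame = TimeFrame(1)
        s, rec = flat_series(frame)
        fv = build_features(s, rec, frame, "daily", toy_model())
        assert len(fv.values) == 1 + frame.end_day

    def test_short_series_rejected(self):
        frame = TimeFrame(8)
        s, rec = flat_series(TimeFrame(0.5))
        with pytest.raises(ValueError, match="restrict"):
            build_features(s, rec, frame, "bmi_last", toy_model())

    def test_unknown_encoding_rejected(self):
        frame = TimeFrame(1)
        s, rec = flat_series(frame)
        with pytest.raises(ValueError, match="encoding"):
            build_features(s, rec, frame, "mystery", toy_model())


class TestStratifiedFolds:
    def test_balanced_classes_give_equal_fold_counts(self):
        labels = np.repeat([f"c{i}" for i in range(5)], 20)
        folds = stratified_folds(labels, 5, seed=0)
        for c in range(5):
            counts = np.bincount(folds[labels == f"c{c}"], minlength=5)
            assert counts.tolist() == [4] * 5

    def test_remainder_distributed_round_robin_from_fold_zero(self):
        folds = stratified_folds(["a"] * 7, 5, seed=1)
        counts = np.bincount(folds, minlength=5)
        assert counts.tolist() == [2, 2, 1, 1, 1]

    def test_deterministic_given_seed(self):
        labels = np.repeat(["x", "y"], 13)
        f1 = stratified_folds(labels, 5, seed=42)
        f2 = stratified_folds(labels, 5, seed=42)
        np.testing.assert_array_equal(f1, f2)

    def test_every_individual_assigned_once(self):
        labels = np.repeat(["a", "b", "c"], 11)
        folds = stratified_folds(labels, 5, seed=3)
        assert ((folds >= 0) & (folds < 5)).all()

    def test_class_smaller_than_fold_count_rejected(self):
        with pytest.raises(TrainingError, match="stratification"):
            stratified_folds(["a"] * 3 + ["b"] * 10, 5, seed=0)


class TestRegressionToClass:
    cutoffs = (-9.2, -2.4, -0.1, 2.2)

    @pytest.mark.parametrize("pred, expect", [
        (-12.0, "high_loss"),
        (-2.4, "moderate_loss"),  # boundary belongs to the loss side
        (-1.0, "insufficient_loss"),
        (0.0, "low_gain"),
        (5.0, "high_gain"),
    ])
    def test_published_cutoffs(self, pred, expect):
        scheme = ClassScheme.five_class()
        assert regression_to_class(pred, self.cutoffs, scheme) == expect

    def test_wrong_cutoff_count_rejected(self):
        with pytest.raises(ValueError):
            regression_to_class(0.0, (-2.4,), ClassScheme.five_class())


class TestSelectFrame:
    @pytest.mark.parametrize("day, months", [
        (105, 4),   # 3.5 months is equidistant to 3 and 4 months; tie -> larger
        (15, 0.5),
        (250, 8),
        (22, 0.5),  # 22 is closer to 15 than 30
        (23, 1),
    ])
    def test_nearest_frame_with_tie_up(self, day, months):
        assert select_frame(day).months == months

    def test_rejects_no_followup(self):
        with pytest.raises(ValueError):
            select_frame(0)


class TestEligibility:
    def test_two_early_entries_eligible_for_half_month(self):
        rec = make_record([(0, 100.0), (10, 99.0)])
        ok, reasons = check_eligibility(rec, TimeFrame(0.5))
        assert ok and reasons == []

    def test_stale_last_entry_ineligible(self):
        rec = make_record([(0, 100.0), (10, 99.0)])
        ok, reasons = check_eligibility(rec, TimeFrame(3))
        assert not ok
        assert any("30 days" in r for r in reasons)

    def test_single_entry_ineligible(self):
        rec = make_record([(0, 100.0)])
        ok, reasons = check_eligibility(rec, TimeFrame(0.5))
        assert not ok
        assert any("2 entries" in r for r in reasons)

    def test_entry_exactly_thirty_days_before_end_is_eligible(self):
        rec = make_record([(0, 100.0), (60, 98.0)])
        ok, _ = check_eligibility(rec, TimeFrame(3))
        assert ok


@pytest.fixture(scope="module")
def tiny_bundle(small_cluster_model):
    """Logistic + linear regression bundle on the session cohort."""
    from weighttraj.modeling import TrainingConfig

    data = small_cluster_model
    return train_bundle(
        data["cohort"],
        methods=("logistic_regression", "linear_regression"),
        cfg=TrainingConfig(seed=5),
        cluster_model=data["model"],
    )


class TestTrainBundle:
    def test_all_frames_and_schemes_present(self, tiny_bundle):
        for m in ("logistic_regression", "linear_regression"):
            for f in FRAME_GRID:
                for k in (3, 5):
                    assert (m, f.end_day, k) in tiny_bundle.models

    def test_cv_accuracy_in_unit_interval(self, tiny_bundle):
        assert all(0.0 <= a <= 1.0 for a in tiny_bundle.cv_accuracy.values())

    def test_training_is_deterministic(self, small_cluster_model):
        from weighttraj.modeling import TrainingConfig

        data = small_cluster_model
        kw = dict(methods=("logistic_regression",),
                  cfg=TrainingConfig(seed=5), cluster_model=data["model"])
        b1 = train_bundle(data["cohort"], **kw)
        b2 = train_bundle(data["cohort"], **kw)
        assert b1.cv_accuracy == b2.cv_accuracy

    def test_longer_followup_does_not_hurt_logistic(self, tiny_bundle):
        assert (tiny_bundle.cv_accuracy[("logistic_regression", 240, 3)]
                >= tiny_bundle.cv_accuracy[("logistic_regression", 15, 3)])

    def test_regression_models_carry_cutoffs(self, tiny_bundle):
        tm = tiny_bundle.get("linear_regression", TimeFrame(8), 5)
        assert tm.cutoffs is not None and len(tm.cutoffs) == 4
        assert (np.diff(tm.cutoffs) > 0).all()

    def test_linear_regression_with_cutoffs_separates_clean_data(self):
        """On noiseless separable data, regression plus optimized cutoffs is
        a perfect training classifier."""
        from weighttraj.clustering import OUTCOME_DAY, optimize_cutoffs
        from sklearn.linear_model import LinearRegression

        rng = np.random.default_rng(0)
        scheme = ClassScheme.five_class()
        y_reg = np.concatenate([rng.uniform(lo, hi, 20) for lo, hi in
                                [(-14, -10), (-8, -6), (-2, 0.5),
                                 (1, 2), (3, 6)]])
        labels = np.repeat(list(scheme.class_names), 20)
        X = y_reg.reshape(-1, 1)  # feature = the target: exactly learnable
        est = LinearRegression().fit(X, y_reg)
        cuts = optimize_cutoffs(est.predict(X), labels, scheme)
        preds = [regression_to_class(p, cuts, scheme) for p in est.predict(X)]
        assert (np.asarray(preds) == labels).all()


class TestPredictIndividual:
    def test_cluster_tracker_gets_its_class(self, tiny_bundle):
        model = tiny_bundle.cluster_model
        days = np.arange(271)
        curve = model.means[0]
        weights = 100.0 * (1 + curve / 100.0)
        rec = make_record([(int(d), float(w))
                           for d, w in zip(days[::7], weights[::7])] +
                          [(270, float(weights[270]))])
        res = predict_individual(rec, tiny_bundle, "logistic_regression")
        assert res.frame.months == 8
        assert res.five_class == model.class_names[0]
        assert res.three_class == "loss"
        assert res.probabilities is not None

    def test_short_followup_reports_three_class_only(self, tiny_bundle):
        rec = make_record([(0, 100.0), (30, 99.0), (58, 98.5)])
        res = predict_individual(rec, tiny_bundle, "logistic_regression")
        assert res.frame.months == 2
        assert res.five_class is None
        assert res.three_class in ("loss", "insufficient_loss", "gain")

    def test_ineligible_individual_raises_with_reasons(self, tiny_bundle):
        # day 250 selects the 8-month frame (end 240), but only the baseline
        # entry falls inside it: both eligibility rules fail
        rec = make_record([(0, 100.0), (250, 95.0)])
        with pytest.raises(EligibilityError):
            predict_individual(rec, tiny_bundle, "logistic_regression")

    def test_prediction_is_deterministic(self, tiny_bundle):
        rec = make_record([(0, 100.0), (100, 95.0), (230, 92.0), (268, 91.0)])
        r1 = predict_individual(rec, tiny_bundle, "linear_regression")
        r2 = predict_individual(rec, tiny_bundle, "linear_regression")
        assert (r1.three_class, r1.five_class) == (r2.three_class, r2.five_class)

    def test_bundle_roundtrips_through_disk(self, tiny_bundle, tmp_path):
        from weighttraj.modeling import ModelBundle

        p = tmp_path / "bundle.joblib"
        tiny_bundle.save(p)
        back = ModelBundle.load(p)
        rec = make_record([(0, 100.0), (100, 95.0), (230, 92.0), (268, 91.0)])
        assert (predict_individual(rec, back, "logistic_regression").three_class
                == predict_individual(rec, tiny_bundle,
                                      "logistic_regression").three_class)
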
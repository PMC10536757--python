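import math

import numpy as np
import pandas as pd
import pytest

from streetscape.modeling import (
    DEFAULT_SWEEP_RADII,
    ConfusionSummary,
    StandardizationStats,
    evaluate_transfer,
    fit_cv,
    mae,
    r2_corr,
    rmse,
    sidewalk_accuracy,
    standardize,
    sweep_buffers,
)


class TestStandardize:
    def test_zscore_with_own_stats(self):
        df = pd.DataFrame({"v": [2.0, 4.0, 6.0]})
        stats = StandardizationStats.fit(df, source="self")
        z = standardize(df, stats)["v"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_variable_rejected_by_name(self):
        df = pd.DataFrame({"flat": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            StandardizationStats.fit(df, source="self")

    def test_training_stats_applied_to_test_data(self):
        train = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0]})  # mean 3, sd ~1.581
        test = pd.DataFrame({"v": [6.0, 7.0]})
        stats = StandardizationStats.fit(train, source="train")
        z = standardize(test, stats)["v"]
        sd = math.sqrt(2.5)
        assert z.tolist() == pytest.approx([(6 - 3) / sd, (7 - 3) / sd])
        assert z.mean() != pytest.approx(0.0, abs=0.1)  # off-centre, as expected
        assert stats.source == "train"


class TestMetrics:
    def test_perfect_predictions(self):
        p = np.array([1.0, 2.0, 3.0])
        assert rmse(p, p) == 0.0
        assert mae(p, p) == 0.0
        assert r2_corr(p, p) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        pred = np.array([1.0, 2.0, 3.0])
        obs = np.array([2.0, 2.0, 2.0])
        assert rmse(pred, obs) == pytest.approx(math.sqrt(2.0 / 3.0))
        assert mae(pred, obs) == pytest.approx(2.0 / 3.0)
        assert r2_corr(pred, obs) == 0.0  # constant observations

    def test_constant_predictions_have_zero_r2(self):
        assert r2_corr(np.array([5.0, 5.0, 5.0]), np.array([1.0, 2.0, 3.0])) == 0.0

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            pred = rng.normal(size=n)
            obs = rng.normal(size=n)
            assert mae(pred, obs) <= rmse(pred, obs) + 1e-12

    def test_rmse_squared_is_mse(self):
        rng = np.random.default_rng(1)
        pred, obs = rng.normal(size=50), rng.normal(size=50)
        assert rmse(pred, obs) ** 2 == pytest.approx(np.mean((pred - obs) ** 2))

    def test_r2_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(2)
        pred, obs = rng.normal(size=50), rng.normal(size=50)
        assert r2_corr(3.0 * pred + 7.0, obs) == pytest.approx(r2_corr(pred, obs))


def _linear_data(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    y = pd.Series(2.0 * X["a"] - X["b"] + noise * rng.normal(size=n))
    return X, y


class TestFitCV:
    def test_realizable_linear_target_fits_exactly(self):
        X, y = _linear_data()
        fit = fit_cv(X, y, family="linear", seed=3)
        assert fit.cv_rmse < 1e-8
        assert fit.cv_r2 == pytest.approx(1.0)

    def test_same_seed_is_bit_identical(self):
        X, y = _linear_data(noise=0.5)
        a = fit_cv(X, y, family="linear", seed=11)
        b = fit_cv(X, y, family="linear", seed=11)
        assert a.cv_rmse == b.cv_rmse and a.cv_r2 == b.cv_r2 and a.cv_mae == b.cv_mae
        assert np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_different_seeds_change_folds(self):
        X, y = _linear_data(noise=0.5)
        a = fit_cv(X, y, family="linear", seed=1)
        b = fit_cv(X, y, family="linear", seed=2)
        assert not np.array_equal(a.fold_assignments, b.fold_assignments)

    @pytest.mark.parametrize("family", ["gbt", "svm"])
    def test_nonlinear_families_run_and_bound_metrics(self, family):
        X, y = _linear_data(noise=0.3)
        fit = fit_cv(X, y, family=family, seed=5)
        assert fit.cv_rmse >= 0 and fit.cv_mae >= 0
        assert 0.0 <= fit.cv_r2 <= 1.0
        assert fit.cv_mae <= fit.cv_rmse + 1e-12

    def test_too_few_rows_rejected(self):
        X, y = _linear_data(n=3)
        with pytest.raises(ValueError, match="smaller than k"):
            fit_cv(X, y, k=5)

    def test_nonfinite_features_rejected(self):
        X, y = _linear_data(n=10)
        X.loc[0, "a"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_cv(X, y)


class TestTransfer:
    def test_same_city_consistency(self):
        X, y = _linear_data(noise=0.2, seed=8)
        fit = fit_cv(X, y, family="linear", seed=8)
        res = evaluate_transfer(fit, X, y)
        pred = fit.model.predict(X.to_numpy())
        assert res.test_rmse == pytest.approx(rmse(pred, y.to_numpy()))
        assert res.calibration_gap == pytest.approx(0.0, abs=1e-9)

    def test_shifted_target_moves_calibration_gap(self):
        X, y = _linear_data(noise=0.2, seed=9)
        fit = fit_cv(X, y, family="linear", seed=9)
        sd = y.std(ddof=1)
        res = evaluate_transfer(fit, X, y + 0.5 * sd)
        assert res.calibration_gap == pytest.approx(-0.5 * sd, rel=1e-6)

    def test_column_mismatch_rejected(self):
        X, y = _linear_data()
        fit = fit_cv(X, y, family="linear")
        with pytest.raises(ValueError, match="columns"):
            evaluate_transfer(fit, X.rename(columns={"a": "c"}), y)


class TestSweep:
    def test_default_radius_set_is_forty_values(self):
        assert len(DEFAULT_SWEEP_RADII) == 40
        assert DEFAULT_SWEEP_RADII[0] == 50
        assert DEFAULT_SWEEP_RADII[-1] == 2000
        steps = set(np.diff(DEFAULT_SWEEP_RADII))
        assert steps == {50}

    def test_flat_performance_selects_smallest_radius(self):
        # constant image features => identical zone features at every radius
        # => identical cv error; the 1-SE rule must prefer the smallest
        rng = np.random.default_rng(4)
        anchors = pd.DataFrame(
            {"id": [f"i{k}" for k in range(30)],
             "x": rng.uniform(0, 500, 30), "y": rng.uniform(0, 500, 30)}
        )
        pc = pd.DataFrame(
            {"point_id": [f"p{k}" for k in range(40)],
             "x": rng.uniform(0, 500, 40), "y": rng.uniform(0, 500, 40)}
        )
        img = pd.DataFrame({"point_id": pc["point_id"], "road": 0.3})
        target = pd.Series(rng.normal(size=30), index=anchors["id"])
        res = sweep_buffers(
            anchors, pc, img, target, radii=(800, 900, 1000), seed=4
        )
        assert res.selected_radius == 800.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sweep_buffers(
                pd.DataFrame({"id": [], "x": [], "y": []}),
                pd.DataFrame({"point_id": [], "x": [], "y": []}),
                pd.DataFrame({"point_id": []}),
                pd.Series(dtype=float),
                radii=(0, 100),
            )


class TestSidewalkAccuracy:
    def test_perfect_labels(self):
        truth = {"a": True, "b": False, "c": True}
        res = sidewalk_accuracy(truth, truth)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_reported_operating_point(self):
        # tp=9, fn=1, tn=13, fp=7 -> sensitivity 0.90, specificity 0.65
        truth, pred = {}, {}
        k = 0
        for tp_fp_tn_fn, (t, p) in (
            (9, (True, True)), (1, (True, False)),
            (13, (False, False)), (7, (False, True)),
        ):
            for _ in range(tp_fp_tn_fn):
                truth[f"s{k}"] = t
                pred[f"s{k}"] = p
                k += 1
        res = sidewalk_accuracy(pred, truth)
        assert (res.tp, res.fn, res.tn, res.fp) == (9, 1, 13, 7)
        assert res.sensitivity == pytest.approx(0.90)
        assert res.specificity == pytest.approx(0.65)
        assert res.total == len(truth)

    def test_all_positive_predictor(self):
        truth = {"a": True, "b": False}
        pred = {"a": True, "b": True}
        res = sidewalk_accuracy(pred, truth)
        assert res.sensitivity == 1.0 and res.specificity == 0.0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sidewalk_accuracy({"a": True}, {"b": True})


def test_confusion_invariants():
    c = ConfusionSummary(tp=3, fp=2, tn=4, fn=1)
    assert c.sensitivity == pytest.approx(3 / 4)
    assert c.specificity == pytest.approx(4 / 6)
    assert c.total == 10
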
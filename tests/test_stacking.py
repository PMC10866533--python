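"""Out-of-fold bookkeeping, meta features, meta fit and the full pipeline."""

import numpy as np
import pytest

from glucostack.series import InsufficientDataError
from glucostack.stacking import (
    AWDStackingRegressor,
    StackingPlan,
    assemble_meta_features,
    extract_block,
    fit_meta,
    kfold_oof,
    kfold_slices,
    meta_predict,
    run_awd_stacking,
)
from glucostack.stacking import test_predictions as fold_average_predictions
from glucostack.synthetic import SynthConfig, generate_cgm


class TestFolds:
    def test_even_split_100_by_5(self):
        slices = kfold_slices(100, 5)
        assert [s.stop - s.start for s in slices] == [20] * 5

    def test_remainder_goes_to_first_fold(self):
        slices = kfold_slices(101, 5)
        assert [s.stop - s.start for s in slices] == [21, 20, 20, 20, 20]

    def test_folds_partition_contiguously(self):
        slices = kfold_slices(37, 5)
        covered = np.concatenate([np.arange(s.start, s.stop) for s in slices])
        np.testing.assert_array_equal(covered, np.arange(37))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            kfold_slices(3, 5)


class TestOof:
    def test_every_sample_predicted_exactly_once(self, linear_factory):
        rng = np.random.default_rng(0)
        X, Y = rng.random((40, 6)), rng.random((40, 6))
        plan = StackingPlan(base_factory=linear_factory, seed=0)
        oof, fold_models = kfold_oof(X, Y, plan)
        assert set(oof) == {"bilstm", "stacklstm", "vlstm"}
        for arch, preds in oof.items():
            assert preds.shape == Y.shape
            assert np.isfinite(preds).all()
            assert len(fold_models[arch]) == 5

    def test_constant_target_oof_predictions_recover_constant(self, linear_factory):
        X = np.random.default_rng(1).random((30, 6))
        Y = np.full((30, 6), 0.4)
        plan = StackingPlan(base_factory=linear_factory)
        oof, _ = kfold_oof(X, Y, plan)
        for preds in oof.values():
            np.testing.assert_allclose(preds, 0.4, atol=0.05)


class TestTestPredictions:
    class _Fixed:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full((len(X), 2), self.value)

    def test_fold_average_is_elementwise_mean(self):
        models = {"m": [self._Fixed(v) for v in (0, 0, 0, 0, 5)]}
        out = fold_average_predictions(models, np.zeros((3, 6)))
        np.testing.assert_allclose(out["m"], 1.0)

    def test_identical_fold_models_average_to_single_output(self):
        models = {"m": [self._Fixed(2.5)] * 5}
        out = fold_average_predictions(models, np.zeros((4, 6)))
        np.testing.assert_allclose(out["m"], 2.5)


class TestMetaFeatures:
    def test_column_count_h6_p6(self):
        preds = [(f"m{i}", np.zeros((10, 6))) for i in range(3)]
        F, bmap = assemble_meta_features(preds, np.zeros((10, 6)), np.zeros((10, 6)))
        assert F.shape == (10, 6 + 4 * 6)

    def test_column_count_h18_p12(self):
        preds = [(f"m{i}", np.zeros((4, 12))) for i in range(3)]
        F, _ = assemble_meta_features(preds, np.zeros((4, 12)), np.zeros((4, 18)))
        assert F.shape == (4, 18 + 4 * 12)

    def test_weighted_block_omitted(self):
        preds = [(f"m{i}", np.zeros((4, 6))) for i in range(3)]
        F, bmap = assemble_meta_features(preds, None, np.zeros((4, 9)))
        assert F.shape == (4, 9 + 3 * 6)
        assert "weighted" not in bmap

    def test_block_round_trip(self):
        rng = np.random.default_rng(0)
        blocks = {f"m{i}": rng.random((5, 6)) for i in range(3)}
        weighted = rng.random((5, 6))
        original = rng.random((5, 9))
        F, bmap = assemble_meta_features(list(blocks.items()), weighted, original)
        for name, mat in blocks.items():
            np.testing.assert_array_equal(extract_block(F, bmap, name), mat)
        np.testing.assert_array_equal(extract_block(F, bmap, "weighted"), weighted)
        np.testing.assert_array_equal(extract_block(F, bmap, "original"), original)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            assemble_meta_features([("m", np.zeros((4, 6)))], np.zeros((5, 6)), None)


class TestMetaModel:
    def test_exact_linear_representability_zero_residual(self):
        rng = np.random.default_rng(0)
        base = rng.random((30, 6))
        F, _ = assemble_meta_features([("m1", base), ("m2", rng.random((30, 6)))],
                                      None, rng.random((30, 6)))
        model = fit_meta(F, base)  # Y equals the m1 block exactly
        np.testing.assert_allclose(meta_predict(model, F), base, atol=1e-8)

    def test_planted_linear_model_recovery(self):
        rng = np.random.default_rng(1)
        weighted = rng.random((50, 6))
        Y = 2.0 * weighted + 1.0
        model = fit_meta(weighted, Y)
        np.testing.assert_allclose(np.diag(model.coef_), 2.0, atol=1e-6)
        np.testing.assert_allclose(model.intercept_, 1.0, atol=1e-6)

    def test_constant_target_single_column(self):
        F = np.random.default_rng(2).random((20, 1))
        Y = np.full((20, 1), 3.0)
        model = fit_meta(F, Y)
        assert model.coef_[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert model.intercept_[0] == pytest.approx(3.0)

    def test_underdetermined_design_warns(self, caplog):
        import logging
        F = np.random.default_rng(3).random((5, 10))
        with caplog.at_level(logging.WARNING, logger="glucostack.stacking"):
            fit_meta(F, np.random.default_rng(4).random((5, 2)))
        assert "pseudoinverse" in caplog.text


class TestAWDStackingRegressor:
    def _fit(self, linear_factory, n=80, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n + 12)
        series = 0.5 + 0.3 * np.sin(2 * np.pi * t / 36) + rng.normal(0, 0.01, n + 12)
        from glucostack.windowing import sliding_windows
        X, Y = sliding_windows(series, 6, 6)
        plan = StackingPlan(base_factory=linear_factory, seed=seed)
        return AWDStackingRegressor(plan=plan).fit(X, Y), X, Y

    def test_fitted_attributes_and_weight_simplex(self, linear_factory):
        reg, X, Y = self._fit(linear_factory)
        assert set(reg.oof_) == {"bilstm", "stacklstm", "vlstm"}
        assert reg.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert (reg.weights_ >= 0).all()
        pred = reg.predict(X[:5])
        assert pred.shape == (5, 6)

    def test_refit_is_deterministic(self, linear_factory):
        rega, X, _ = self._fit(linear_factory, seed=3)
        regb, _, _ = self._fit(linear_factory, seed=3)
        np.testing.assert_array_equal(rega.weights_, regb.weights_)
        np.testing.assert_array_equal(rega.predict(X[:4]), regb.predict(X[:4]))


class TestFullPipeline:
    @pytest.fixture(scope="class")
    def runs(self):
        # class-scoped: one train series, two different test series
        from sklearn.linear_model import LinearRegression

        class LinearBase:
            def fit(self, X, y, *, X_val=None, y_val=None):
                self._lr = LinearRegression().fit(X, y)
                return self

            def predict(self, X):
                return self._lr.predict(np.asarray(X, dtype=float))

        linear_factory = lambda arch, p, seed: LinearBase()  # noqa: E731
        train = generate_cgm(SynthConfig(duration_days=2, seed=10), role="train")
        test_a = generate_cgm(SynthConfig(duration_days=1, seed=20), role="test")
        test_b = generate_cgm(SynthConfig(duration_days=1, seed=30), role="test")
        plan = StackingPlan(base_factory=linear_factory, seed=0)
        res_a = run_awd_stacking(train, test_a, 30, plan)
        res_b = run_awd_stacking(train, test_b, 30, plan)
        return res_a, res_b

    def test_reports_all_four_history_windows(self, runs):
        res, _ = runs
        assert [w.history_points for w in res.windows] == [6, 9, 12, 18]
        for w in res.windows:
            assert w.stacked.rmse >= 0
            assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mean_metrics_average_windows(self, runs):
        res, _ = runs
        assert res.mean_metrics["rmse"] == pytest.approx(
            np.mean([w.stacked.rmse for w in res.windows]))

    def test_no_test_values_in_fitted_statistics(self, runs):
        # the training series is identical in both runs, so every fitted
        # statistic must be identical even though the test series differ:
        # any dependence on test data would show up here
        res_a, res_b = runs
        assert res_a.fitted["norm_params"] == res_b.fitted["norm_params"]
        for key in ("h6", "h9", "h12", "h18"):
            assert res_a.fitted[key]["weights"] == res_b.fitted[key]["weights"]
            np.testing.assert_array_equal(res_a.fitted[key]["meta_coef"],
                                          res_b.fitted[key]["meta_coef"])
            np.testing.assert_array_equal(res_a.fitted[key]["meta_intercept"],
                                          res_b.fitted[key]["meta_intercept"])

    def test_manifest_is_json_serializable(self, runs):
        import json
        res, _ = runs
        text = json.dumps(res.to_manifest(), sort_keys=True)
        assert "mean_metrics" in text
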
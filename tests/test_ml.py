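import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import ParameterGrid

from conncog.ml import (
    CLASSIFIERS,
    REGRESSORS,
    DeconfoundSpec,
    FoldResult,
    ModelConfig,
    build_grid,
    deconfound_target,
    fit_classify,
    fit_predict_concat,
    fit_predict_stacking,
    make_cv_plan,
    make_estimator,
    summarize,
    summarize_frame,
    fold_results_frame,
)

SMALL_RIDGE = ModelConfig("ridge", hyper_grid={"alpha": [1.0, 100.0]})


def _confounds(n, rng):
    return pd.DataFrame(
        {
            "age": rng.uniform(55, 85, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.integers(1, 9, n).astype(float),
            "etiv": rng.normal(1500, 100, n),
        }
    )


class TestCVPlan:
    def test_entry_count(self):
        plan = make_cv_plan(594, outer_k=10, repeats=10, seed=0)
        assert len(plan.outer) == 100

    def test_each_subject_tested_once_per_repeat(self):
        plan = make_cv_plan(120, outer_k=10, repeats=10, seed=1)
        counts = np.zeros(120, dtype=int)
        for _, _, train, test in plan.outer:
            assert np.intersect1d(train, test).size == 0
            counts[test] += 1
        assert np.all(counts == 10)

    def test_exact_fold_sizes(self):
        plan = make_cv_plan(100, outer_k=10, repeats=1, seed=0)
        assert all(test.size == 10 for _, _, _, test in plan.outer)

    def test_partition_per_repeat(self):
        plan = make_cv_plan(47, outer_k=5, repeats=3, seed=2)
        for rep in range(3):
            tested = np.concatenate(
                [test for r, _, _, test in plan.outer if r == rep]
            )
            assert sorted(tested) == list(range(47))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(5, outer_k=10)

    def test_deterministic(self):
        a = make_cv_plan(50, outer_k=5, repeats=2, seed=3)
        b = make_cv_plan(50, outer_k=5, repeats=2, seed=3)
        for (r1, f1, tr1, te1), (r2, f2, tr2, te2) in zip(a.outer, b.outer):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)


class TestGrids:
    def test_rf_grid_size(self):
        assert len(list(ParameterGrid(build_grid("rf")))) == 14

    def test_en_grid_size(self):
        assert len(list(ParameterGrid(build_grid("en")))) == 100

    def test_linsvr_endpoints(self):
        grid = build_grid("linsvr")["C"]
        assert len(grid) == 10
        assert grid[0] == pytest.approx(1e-4)
        assert grid[-1] == pytest.approx(1e1)

    def test_ridge_lasso_ranges(self):
        assert build_grid("ridge")["alpha"][0] == pytest.approx(1e-3)
        assert build_grid("ridge")["alpha"][-1] == pytest.approx(1e5)
        assert build_grid("lasso")["alpha"][0] == pytest.approx(1e-1)
        assert build_grid("lasso")["alpha"][-1] == pytest.approx(1e2)

    def test_rf_depths(self):
        assert build_grid("rf")["max_depth"] == [4, 6, 8, 10, 20, 40, None]

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            build_grid("xgboost")

    @pytest.mark.parametrize("alg", REGRESSORS + CLASSIFIERS)
    def test_every_algorithm_instantiable(self, alg):
        params = dict(list(ParameterGrid(build_grid(alg)))[0])
        est = make_estimator(alg, params, seed=0)
        assert est is not None


class TestDeconfoundTarget:
    def test_uncorrelated_confound_keeps_variance(self, rng):
        y = rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        tr = np.arange(1500)
        te = np.arange(1500, 2000)
        y_tr, _ = deconfound_target(y, c, tr, te)
        assert y_tr.var() == pytest.approx(y[tr].var(), rel=0.02)

    def test_exact_linear_recovery(self, rng):
        age = rng.uniform(55, 85, 100)
        y = 2.0 * age
        tr, te = np.arange(70), np.arange(70, 100)
        y_tr, y_te = deconfound_target(y, age, tr, te)
        np.testing.assert_allclose(y_tr, 0, atol=1e-8)
        np.testing.assert_allclose(y_te, 0, atol=1e-8)

    def test_etiv_in_both_modes(self):
        assert "etiv" in DeconfoundSpec("no_deconf").confound_columns()
        assert "etiv" in DeconfoundSpec("deconf").confound_columns()
        assert set(DeconfoundSpec("deconf").confound_columns()) == {
            "etiv", "age", "sex", "education",
        }

    def test_train_only_fitting(self, rng):
        # perturbing test rows must not change the train-side residuals
        y = rng.standard_normal(100)
        c = rng.standard_normal(100)
        tr, te = np.arange(80), np.arange(80, 100)
        ref_tr, _ = deconfound_target(y, c, tr, te)
        y2, c2 = y.copy(), c.copy()
        y2[te] += 100
        c2[te] -= 50
        new_tr, _ = deconfound_target(y2, c2, tr, te)
        np.testing.assert_allclose(ref_tr, new_tr, atol=1e-12)

    def test_rank_deficient_warns(self, rng):
        y = rng.standard_normal(50)
        c = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            deconfound_target(y, c, np.arange(40), np.arange(40, 50))


class TestConcat:
    def test_realizable_linear_signal(self, rng):
        n, p = 120, 5
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        plan = make_cv_plan(n, outer_k=5, repeats=1, seed=0)
        res = fit_predict_concat(X, y, SMALL_RIDGE, plan)
        assert summarize(res).mean_r2 > 0.99

    def test_dummy_reference_present(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        plan = make_cv_plan(60, outer_k=5, repeats=1, seed=0)
        res = fit_predict_concat(X, y, SMALL_RIDGE, plan)
        for f in res:
            assert np.isfinite(f.dummy_mae) and np.isfinite(f.dummy_r2)
            assert f.dummy_r2 <= 0.01  # train-mean predictor

    def test_nan_features_rejected(self):
        X = np.ones((30, 3))
        X[0, 0] = np.nan
        plan = make_cv_plan(30, outer_k=3, repeats=1, seed=0)
        with pytest.raises(ValueError, match="NaN"):
            fit_predict_concat(X, np.zeros(30), SMALL_RIDGE, plan)

    def test_deconfounding_within_pipeline(self, rng):
        # target purely from confounds: deconf kills the signal even
        # when demographics enter as extra features
        n = 150
        conf = _confounds(n, rng)
        y = 0.8 * (conf["age"] - 70) / 10 + 0.1 * rng.standard_normal(n)
        X = rng.standard_normal((n, 20))
        plan = make_cv_plan(n, outer_k=5, repeats=1, seed=1)
        extra = conf[["age", "sex", "education"]]
        no_deconf = fit_predict_concat(
            X, y.to_numpy(), SMALL_RIDGE, plan,
            DeconfoundSpec("no_deconf"), conf, extra_features=extra,
        )
        deconf = fit_predict_concat(
            X, y.to_numpy(), SMALL_RIDGE, plan,
            DeconfoundSpec("deconf"), conf, extra_features=extra,
        )
        assert summarize(no_deconf).mean_r2 > 0.5
        assert summarize(deconf).mean_r2 <= 0.05

    def test_determinism(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        plan = make_cv_plan(50, outer_k=5, repeats=1, seed=4)
        a = fit_predict_concat(X, y, SMALL_RIDGE, plan)
        b = fit_predict_concat(X, y, SMALL_RIDGE, plan)
        for fa, fb in zip(a, b):
            assert fa.mae == fb.mae and fa.r2 == fb.r2
            assert fa.chosen_params == fb.chosen_params

    def test_coefficients_stored(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        plan = make_cv_plan(40, outer_k=4, repeats=1, seed=0)
        res = fit_predict_concat(X, y, SMALL_RIDGE, plan, store_coefs=True)
        assert all(f.coef is not None and f.coef.shape == (6,) for f in res)

    def test_leakage_sentinel_small(self, rng):
        # permuted target: mean R^2 must not be meaningfully positive
        r2s = []
        for seed in range(3):
            g = np.random.default_rng(seed)
            X = g.standard_normal((80, 120))
            y = g.standard_normal(80)
            plan = make_cv_plan(80, outer_k=5, repeats=1, seed=seed)
            r2s.append(summarize(fit_predict_concat(X, y, SMALL_RIDGE, plan)).mean_r2)
        assert np.mean(r2s) <= 0.05


class TestStacking:
    def test_layer2_width_equals_modalities(self, rng):
        n = 60
        blocks = {m: rng.standard_normal((n, 10)) for m in ("fc", "sc", "gmv")}
        y = rng.standard_normal(n)
        plan = make_cv_plan(n, outer_k=4, repeats=1, inner_k=3, seed=0)
        res = fit_predict_stacking(
            blocks, y, SMALL_RIDGE, plan,
            meta_grid={"n_estimators": [50], "max_depth": [4]},
            store_coefs=True,
        )
        assert all(f.coef.shape == (3,) for f in res)

    def test_fold_exclusivity_across_layers(self, rng):
        n = 50
        blocks = {"a": rng.standard_normal((n, 8)), "b": rng.standard_normal((n, 8))}
        y = rng.standard_normal(n)
        plan = make_cv_plan(n, outer_k=5, repeats=2, inner_k=3, seed=1)
        log: list = []
        fit_predict_stacking(
            blocks, y, SMALL_RIDGE, plan,
            meta_grid={"n_estimators": [20], "max_depth": [4]},
            structure_log=log,
        )
        assert len(log) == 10
        for entry in log:
            test = set(entry["test_idx"].tolist())
            assert not test & set(entry["meta_train"].tolist())
            for l1_train in entry["layer1_train"]:
                assert not test & set(l1_train.tolist())

    def test_informative_modality_recovery(self):
        # one informative modality + two noise blocks: stacked R^2 close
        # to the informative single-modality R^2
        deltas = []
        for seed in range(3):
            g = np.random.default_rng(seed + 100)
            n = 200
            signal = g.standard_normal((n, 10))
            beta = g.standard_normal(10)
            lin = signal @ beta
            lin = (lin - lin.mean()) / lin.std()
            y = np.sqrt(0.4) * lin + np.sqrt(0.6) * g.standard_normal(n)
            blocks = {
                "info": signal,
                "noise1": g.standard_normal((n, 10)),
                "noise2": g.standard_normal((n, 10)),
            }
            plan = make_cv_plan(n, outer_k=5, repeats=1, inner_k=3, seed=seed)
            single = summarize(
                fit_predict_concat(signal, y, SMALL_RIDGE, plan)
            ).mean_r2
            stacked = summarize(
                fit_predict_stacking(
                    blocks, y, SMALL_RIDGE, plan,
                    meta_grid={"n_estimators": [100], "max_depth": [4]},
                )
            ).mean_r2
            deltas.append(stacked - single)
        assert abs(np.mean(deltas)) < 0.1

    def test_single_modality_rejected(self, rng):
        plan = make_cv_plan(30, outer_k=3, repeats=1, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            fit_predict_stacking(
                {"only": rng.standard_normal((30, 5))},
                rng.standard_normal(30), SMALL_RIDGE, plan,
            )

    def test_subject_mismatch_rejected(self, rng):
        plan = make_cv_plan(30, outer_k=3, repeats=1, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            fit_predict_stacking(
                {"a": rng.standard_normal((30, 5)), "b": rng.standard_normal((29, 5))},
                rng.standard_normal(30), SMALL_RIDGE, plan,
            )

    def test_extra_features_form_block(self, rng):
        n = 40
        blocks = {"a": rng.standard_normal((n, 5)), "b": rng.standard_normal((n, 5))}
        extra = _confounds(n, rng)[["age", "sex", "education"]]
        plan = make_cv_plan(n, outer_k=4, repeats=1, inner_k=3, seed=0)
        res = fit_predict_stacking(
            blocks, rng.standard_normal(n), SMALL_RIDGE, plan,
            extra_features=extra,
            meta_grid={"n_estimators": [20], "max_depth": [4]},
            store_coefs=True,
        )
        assert all(f.coef.shape == (3,) for f in res)  # a, b, extra


class TestClassification:
    def test_perfectly_separable(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 3)) + 10 * y[:, None]
        plan = make_cv_plan(n, outer_k=5, repeats=1, inner_k=3, seed=0)
        cfg = ModelConfig("logistic", hyper_grid={"C": [1.0]})
        res = fit_classify(X, y, cfg, plan)
        assert all(f.accuracy == 1.0 for f in res)

    def test_chance_level_on_independent_labels(self):
        accs = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            n = 100
            y = np.repeat([0, 1], n // 2)
            g.shuffle(y)
            X = g.standard_normal((n, 20))
            plan = make_cv_plan(n, outer_k=5, repeats=1, inner_k=3, seed=seed)
            cfg = ModelConfig("ridgeclf", hyper_grid={"alpha": [1.0]})
            accs.extend(f.accuracy for f in fit_classify(X, y, cfg, plan))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_dummy_majority_on_balanced_groups(self, rng):
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 5))
        plan = make_cv_plan(n, outer_k=4, repeats=1, inner_k=3, seed=0)
        cfg = ModelConfig("linsvc", hyper_grid={"C": [1.0]})
        res = fit_classify(X, y, cfg, plan)
        assert abs(np.mean([f.dummy_accuracy for f in res]) - 0.5) < 0.15

    def test_nonbinary_labels_rejected(self, rng):
        plan = make_cv_plan(30, outer_k=3, repeats=1, seed=0)
        with pytest.raises(ValueError, match="binary"):
            fit_classify(
                rng.standard_normal((30, 3)), np.arange(30),
                ModelConfig("logistic", hyper_grid={"C": [1.0]}), plan,
            )


class TestSummarize:
    def _fold(self, r2, dummy_r2=0.0, mae=1.0, dummy_mae=1.0):
        return FoldResult(0, 0, mae, r2, 0.0, dummy_mae, dummy_r2, {}, 10)

    def test_model_identical_to_dummy_strict_comparison(self):
        folds = [self._fold(0.0, dummy_r2=0.0) for _ in range(4)]
        assert summarize(folds).pct_folds_r2_better == 0.0

    def test_hand_listed_means(self):
        folds = [
            FoldResult(0, i, mae, r2, r, 1.0, 0.0, {}, 10)
            for i, (mae, r2, r) in enumerate(
                [(0.7, 0.1, 0.3), (0.8, 0.2, 0.4), (0.9, -0.1, 0.1), (0.6, 0.3, 0.5)]
            )
        ]
        s = summarize(folds)
        assert s.mean_mae == pytest.approx((0.7 + 0.8 + 0.9 + 0.6) / 4)
        assert s.mean_r2 == pytest.approx((0.1 + 0.2 - 0.1 + 0.3) / 4)
        assert s.mean_r == pytest.approx((0.3 + 0.4 + 0.1 + 0.5) / 4)
        assert s.pct_folds_r2_better == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_frame_round_trip(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        plan = make_cv_plan(40, outer_k=4, repeats=1, seed=0)
        res = fit_predict_concat(X, y, SMALL_RIDGE, plan)
        direct = summarize(res)
        via_frame = summarize_frame(fold_results_frame(res))
        assert via_frame.mean_r2 == pytest.approx(direct.mean_r2)
        assert via_frame.pct_folds_r2_better == direct.pct_folds_r2_better
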
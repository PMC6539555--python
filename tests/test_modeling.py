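import numpy as np
import pytest

from qsarspace.featurize import FeatureMatrix
from qsarspace.modeling import (MetricPCASpace, SVMSpec, SelectedFeatureSpace,
                                VectorPCASpace, default_k_schedule, evaluate,
                                feedforward_select, fit_final, rf_rank)


def bit_fm(rows, ids=None, rep="ecfp"):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"m{i}" for i in range(rows.shape[0])]
    return FeatureMatrix(rows, [f"b{i}" for i in range(rows.shape[1])], rep, ids)


class TestRFRank:
    def test_exact_copy_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 20))
        y = X[:, 1].copy()
        ranked = rf_rank(X, y, seed=0, n_estimators=100, n_repeats=3)
        assert ranked.order[0] == 1

    def test_identical_columns_tie_broken_by_index(self):
        col = np.random.default_rng(1).normal(size=60)
        X = np.column_stack([col] * 4)
        y = col + np.random.default_rng(2).normal(0, 0.01, 60)
        ranked = rf_rank(X, y, seed=0, n_estimators=50, n_repeats=2)
        a = rf_rank(X, y, seed=0, n_estimators=50, n_repeats=2)
        assert np.array_equal(ranked.order, a.order)  # deterministic under seed

    def test_column_permutation_permutes_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 8))
        y = 2 * X[:, 0] + X[:, 5] + rng.normal(0, 0.1, 200)
        base = rf_rank(X, y, seed=0, n_estimators=100, n_repeats=3)
        perm = np.array([3, 0, 1, 2, 7, 4, 5, 6])
        permuted = rf_rank(X[:, perm], y, seed=0, n_estimators=100, n_repeats=3)
        assert set(perm[permuted.order[:2]]) == set(base.order[:2])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            rf_rank(np.zeros((5, 3)), np.zeros(5))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0.1, 0.5, 0.9])
        pve, rmse = evaluate(y, y)
        assert pve == pytest.approx(1.0) and rmse == 0.0

    def test_mean_prediction_gives_zero_pve(self):
        y = np.array([0.0, 0.5, 1.0])
        pve, _ = evaluate(y, np.full(3, y.mean()))
        assert pve == pytest.approx(0.0)

    def test_hand_computed_four_point_example(self):
        y = np.array([0.0, 0.25, 0.5, 1.0])
        yhat = np.array([0.1, 0.25, 0.4, 0.9])
        pve, rmse = evaluate(y, yhat)
        assert rmse == pytest.approx(np.sqrt(0.03 / 4))       # 0.0866...
        assert pve == pytest.approx(1 - 0.03 / 0.546875)      # 0.94514...

    def test_constant_truth_has_undefined_pve(self):
        pve, rmse = evaluate(np.full(4, 0.5), np.array([0.4, 0.5, 0.6, 0.5]))
        assert pve is None and rmse > 0


class TestFeedforwardSelect:
    def test_single_dimension_chooses_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] + rng.normal(0, 0.1, 40)).clip(-3, 3)
        space = SelectedFeatureSpace(X, np.array([0]))
        curve = feedforward_select(space, y, [1], folds=4, seed=0)
        assert curve.chosen_k == 1

    def test_informative_prefix_selected_on_synthetic_signal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 15))
        y = X[:, 0] + 0.8 * X[:, 1] + 0.6 * X[:, 2] + rng.normal(0, 0.05, 400)
        space = SelectedFeatureSpace(X, np.arange(15))
        curve = feedforward_select(space, y, list(range(1, 11)), folds=5, seed=0)
        assert 2 <= curve.chosen_k <= 6

    def test_curve_contract(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 8))
        y = X[:, 0] + rng.normal(0, 0.2, 60)
        ks = [1, 2, 4, 8]
        curve = feedforward_select(SelectedFeatureSpace(X, np.arange(8)), y,
                                   ks, folds=3, seed=0)
        assert curve.k_values == ks
        assert len(curve.mean_cv_rmse) == len(ks)
        chosen_idx = curve.k_values.index(curve.chosen_k)
        assert curve.mean_cv_rmse[chosen_idx] == curve.mean_cv_rmse.min()

    def test_constant_fold_y_rejected(self):
        X = np.random.default_rng(7).normal(size=(20, 3))
        with pytest.raises(ValueError, match="distinct"):
            feedforward_select(SelectedFeatureSpace(X, np.arange(3)),
                               np.full(20, 0.5), [1], folds=2, seed=0)


class TestFitFinal:
    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 50)
        preds = []
        for _ in range(2):
            space = SelectedFeatureSpace(X, np.arange(5))
            model = fit_final(space, y, 3)
            preds.append(model.predict(X[:10]))
        assert np.array_equal(preds[0], preds[1])

    def test_constant_y_rejected(self):
        space = SelectedFeatureSpace(np.zeros((20, 2)), np.arange(2))
        with pytest.raises(ValueError, match="constant"):
            fit_final(space, np.full(20, 0.5), 1)

    def test_training_error_tracks_noise_level(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 4))
        noise_sd = 0.2  # well above the SVR epsilon-tube (0.1)
        y = X[:, 0] + rng.normal(0, noise_sd, 200)
        model = fit_final(SelectedFeatureSpace(X, np.arange(4)), y, 4,
                          SVMSpec())
        _, rmse = evaluate(y, model.predict(X))
        assert rmse < 1.5 * noise_sd


class TestMetricPCASpace:
    def test_fold_refit_excludes_held_out_molecules(self):
        rng = np.random.default_rng(10)
        rows = (rng.random((30, 64)) < 0.3).astype(float)
        fm = bit_fm(rows)
        space = MetricPCASpace(fm, fm.mol_ids, refit_per_fold=True)
        tr = np.arange(20)
        te = np.arange(20, 30)
        Xtr, Xte = space.fold(tr, te, 5)
        # fold-train scores must equal a PCA fitted on the fold-train block only
        from qsarspace.pca import fit_pca
        model, scores = fit_pca(space.square.values[np.ix_(tr, tr)],
                                n_components=5)
        assert np.allclose(Xtr, scores.scores, atol=1e-9)
        assert Xte.shape == (10, 5)

    def test_query_projection_uses_cross_similarities(self):
        rng = np.random.default_rng(11)
        rows = (rng.random((25, 64)) < 0.3).astype(float)
        ids = [f"m{i}" for i in range(25)]
        fm = bit_fm(rows, ids)
        train_ids, query_ids = ids[:20], ids[20:]
        space = MetricPCASpace(fm, train_ids)
        y = rng.uniform(0, 1, 20)
        model = fit_final(space, y, 3)
        preds = model.predict(query_ids)
        assert preds.shape == (5,)

    def test_pure_noise_cv_pve_stays_low(self, default_synth, default_curated):
        """Leakage guard: fold-wise PCA refit must not let noise look predictable."""
        ds = default_curated
        rng = np.random.default_rng(99)
        y_noise = rng.uniform(0.2, 0.8, len(ds.train_ids))
        space = MetricPCASpace(default_synth.bit_matrix(ds.train_ids),
                               ds.train_ids)
        curve = feedforward_select(space, y_noise,
                                   default_k_schedule(20, 20, 5), folds=5,
                                   seed=17)
        assert np.nanmax(curve.mean_cv_pve) <= 0.1


def test_default_k_schedule_shape():
    assert default_k_schedule(10) == list(range(1, 11))
    sched = default_k_schedule(50, dense_until=30, step=5)
    assert sched[:30] == list(range(1, 31))
    assert sched[30:] == [35, 40, 45, 50]
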
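"""RBF-SVR training, prediction, ROC/AUC, and repeated k-fold CV."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import orscreen as o
from orscreen.descriptors import DescriptorMatrix

from conftest import pairs_auc


def scaled_matrix(values, seed_names=None):
    values = np.asarray(values, dtype=float)
    names = seed_names or [f"d{j}" for j in range(values.shape[1])]
    m = DescriptorMatrix([f"m{i:03d}" for i in range(values.shape[0])], names, values)
    return o.scale_matrix(m)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = o.roc_auc([2.0, 3.0, 0.0, 1.0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_tie_convention(self):
        _, auc = o.roc_auc([1.0, 1.0], [1, 0])
        assert auc == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.normal(size=30), 1)  # ties likely
        labels = rng.random(30) < 0.4
        labels[:2] = [True, False]
        _, auc = o.roc_auc(scores, labels)
        assert auc == pairs_auc(scores, labels)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        _, auc = o.roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        points, _ = o.roc_auc(scores, labels)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert (np.diff(points[:, 0]) >= 0).all()
        assert (np.diff(points[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            o.roc_auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        labels[:2] = [True, False]
        _, auc = o.roc_auc(scores, labels)
        _, auc2 = o.roc_auc(np.exp(2.0 * scores) + 7.0, labels)
        assert auc == auc2


class TestTrain:
    def test_noiseless_linear_target_fit_within_epsilon(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 2))
        m = scaled_matrix(x)
        y = 3.0 * m.values[:, 0] + 1.0
        model = o.train(m, ["d0", "d1"], y, o.Hyperparams(C=1000.0, epsilon=0.1))
        fitted = o.predict(model, m)
        assert np.abs(fitted - y).max() <= 0.1 + 0.05

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        m = scaled_matrix(rng.normal(size=(20, 3)))
        y = rng.normal(size=20)
        model = o.train(m, m.descriptor_names, y)
        perm = rng.permutation(20)
        m2 = m.take_rows(perm)
        model2 = o.train(m2, m.descriptor_names, y[perm])
        np.testing.assert_allclose(
            o.predict(model, m), o.predict(model2, m), atol=1e-9
        )

    def test_serialization_roundtrip_bitwise(self, tmp_path, panel1, fitted1):
        _, _, work, _, _, _ = panel1
        _, model = fitted1
        p = tmp_path / "model.json"
        model.save(p)
        back = o.TrainedModel.load(p)
        a = o.predict(model, work)
        b = o.predict(back, work)
        assert np.abs(a - b).max() <= 1e-12
        assert back.training_hash == model.training_hash

    def test_too_few_molecules_rejected(self):
        m = scaled_matrix([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            o.train(m, ["d0"], [0.0, 1.0])

    def test_nonfinite_targets_rejected(self):
        m = scaled_matrix(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            o.train(m, ["d0"], [0.0, 1.0, np.nan, 0.0, 1.0])


class TestPredict:
    def test_reproduces_fitted_values(self, panel1, fitted1):
        _, _, work, _, activity, _ = panel1
        subset, model = fitted1
        from sklearn.svm import SVR

        hp = model.hyperparams
        order = np.argsort(np.asarray(work.molecule_ids, dtype=object))
        svr = SVR(kernel="rbf", C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon, tol=1e-6)
        svr.fit(work.columns(subset.selected)[order], activity[order])
        np.testing.assert_allclose(
            o.predict(model, work), svr.predict(work.columns(subset.selected)),
            atol=1e-9,
        )

    def test_duplicated_row_duplicated_score(self, panel1, fitted1):
        _, _, work, _, _, _ = panel1
        _, model = fitted1
        dup = DescriptorMatrix(
            ["x1", "x2"], work.descriptor_names,
            np.vstack([work.values[0], work.values[0]]),
            scaling=work.scaling,
        )
        s = o.predict(model, dup)
        assert s[0] == s[1]

    def test_missing_descriptor_named_in_error(self, fitted1):
        _, model = fitted1
        m = scaled_matrix(np.random.default_rng(0).normal(size=(4, 2)),
                          ["other1", "other2"])
        with pytest.raises(KeyError, match=model.descriptor_names[0]):
            o.predict(model, m)

    def test_holdout_actives_score_higher(self):
        cfg = o.ChemSimConfig(seed=5)
        records, matrix, truth = o.gen_training_set(cfg)
        work = o.scale_matrix(o.clean_matrix(matrix))
        labels = np.array([r.active_label == "active" for r in records])
        activity = np.array([r.activity for r in records])
        subset = o.sfs_select(work, labels, target_size=3)
        model = o.train(work, subset, activity)
        _, libmat, libtruth = o.gen_library(cfg, 500, 50)
        scores = o.predict(model, libmat)
        act = np.isin(libmat.molecule_ids, libtruth.active_ids)
        assert scores[act].mean() > scores[~act].mean()


class TestCrossValidate:
    def test_fold_sizes_differ_by_at_most_one(self, panel1, fitted1):
        _, _, work, labels, activity, _ = panel1
        subset, _ = fitted1
        cv = o.cross_validate(work, subset, activity, labels, k=5, repeats=3, seed=0)
        for r in range(cv.repeats):
            sizes = np.bincount(cv.fold_assignments[r], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_twenty_molecules_five_folds_of_four(self):
        rng = np.random.default_rng(0)
        m = scaled_matrix(rng.normal(size=(20, 2)))
        labels = np.r_[np.ones(8, bool), np.zeros(12, bool)]
        y = labels * 60.0
        cv = o.cross_validate(m, ["d0", "d1"], y, labels, k=5, repeats=2, seed=1)
        for r in range(2):
            assert set(np.bincount(cv.fold_assignments[r])) == {4}

    def test_every_molecule_scored_once_per_repeat(self, panel1, fitted1):
        _, _, work, labels, activity, _ = panel1
        subset, _ = fitted1
        cv = o.cross_validate(work, subset, activity, labels, k=4, repeats=2, seed=2)
        # fold assignment covers all molecules; oof scores all filled
        assert cv.fold_assignments.shape == (2, work.n_molecules)
        assert np.isfinite(cv.oof_scores).all()

    def test_bitwise_determinism(self, panel1, fitted1):
        _, _, work, labels, activity, _ = panel1
        subset, _ = fitted1
        a = o.cross_validate(work, subset, activity, labels, k=4, repeats=3, seed=7)
        b = o.cross_validate(work, subset, activity, labels, k=4, repeats=3, seed=7)
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        assert a.mean_auc == b.mean_auc

    def test_auc_bounds_and_mean(self, panel1, fitted1):
        _, _, work, labels, activity, _ = panel1
        subset, _ = fitted1
        cv = o.cross_validate(work, subset, activity, labels, k=4, repeats=5, seed=0)
        assert ((cv.aucs >= 0) & (cv.aucs <= 1)).all()
        assert cv.mean_auc == pytest.approx(cv.aucs.mean())

    def test_single_class_rejected(self, panel1, fitted1):
        _, _, work, _, activity, _ = panel1
        subset, _ = fitted1
        with pytest.raises(ValueError):
            o.cross_validate(work, subset, activity,
                             np.ones(work.n_molecules, bool), k=4, repeats=1, seed=0)

    def test_report_save(self, tmp_path, panel1, fitted1):
        _, _, work, labels, activity, _ = panel1
        subset, _ = fitted1
        cv = o.cross_validate(work, subset, activity, labels, k=4, repeats=3, seed=0)
        p = tmp_path / "cv.csv"
        cv.save(p)
        text = p.read_text()
        assert "mean_auc" in text and "repeat,auc" in text


def test_grid_search_returns_best_of_grid(panel1, fitted1):
    _, _, work, labels, activity, _ = panel1
    subset, _ = fitted1
    grid = [o.Hyperparams(C=0.1), o.Hyperparams(C=10.0)]
    best, table = o.grid_search(work, subset, activity, labels, grid=grid,
                                k=4, repeats=2, seed=0)
    assert best in grid
    assert len(table) == 2
    assert table["mean_auc"].max() == table.loc[
        table["C"] == best.C, "mean_auc"
    ].iloc[0]
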
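"""Feature reduction, relevance vector regression and brain-age estimation."""

import numpy as np
import pandas as pd
import pytest

import primage as pm
from primage.brainage import (BrainAgeResult, fit_pca_reduction, prepare_map,
                              reduce_features, train_rvr)


def _maps_from_rows(rows, shape=(8, 8, 8)):
    """Turn an (n, p) matrix into n cubic 'GM maps' (p = prod(shape))."""
    return [r.reshape(shape) for r in rows]


def _meta(ages, **cols):
    n = len(ages)
    base = {"id": [f"S{i:02d}" for i in range(n)], "age": ages,
            "sex": ["female"] * n, "group": ["CTR"] * n}
    base.update(cols)
    return pd.DataFrame(base)


class TestReduceFeatures:
    def test_identical_maps_have_zero_variance(self):
        rng = np.random.default_rng(0)
        base = rng.random((6, 6, 6))
        red, scores = reduce_features([base] * 5, np.ones((6, 6, 6), bool),
                                      (3, 3, 3))
        assert np.allclose(red.explained_variance, 0, atol=1e-12)
        assert np.allclose(scores, 0, atol=1e-9)

    def test_rank_two_data_has_two_components(self):
        rng = np.random.default_rng(1)
        u, v = rng.random(216), rng.random(216)
        rows = [a * u + b * v for a, b in rng.random((8, 2))]
        red, _ = reduce_features(_maps_from_rows(np.array(rows), (6, 6, 6)),
                                 np.ones((6, 6, 6), bool), (3, 3, 3))
        assert (red.explained_variance > 1e-8).sum() == 2
        assert np.all(red.explained_variance[2:] < 1e-8)

    def test_reconstruction_error_equals_discarded_eigenvalues(self):
        """Truncated-PCA identity against an eigendecomposition oracle."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 216))
        maps = _maps_from_rows(X, (6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        k = 4
        red, scores = reduce_features(maps, mask, (3, 3, 3), n_components=k)
        # same deterministic per-map preparation, independent eigen-oracle
        Xs = np.stack([prepare_map(m, (3, 3, 3), 3.0, 3.0, red.resampled_mask)
                       for m in maps])
        Xc = Xs - Xs.mean(axis=0)
        recon = scores @ red.pca_basis
        err = np.sum((Xc - recon) ** 2) / (X.shape[0] - 1)
        evals = np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1))[::-1]
        assert err == pytest.approx(float(evals[k:].sum()), abs=1e-6)

    def test_components_orthonormal_and_variances_sorted(self):
        rng = np.random.default_rng(3)
        maps = _maps_from_rows(rng.normal(size=(9, 216)), (6, 6, 6))
        red, _ = reduce_features(maps, np.ones((6, 6, 6), bool), (3, 3, 3))
        gram = red.pca_basis @ red.pca_basis.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert np.all(np.diff(red.explained_variance) <= 1e-10)
        assert red.n_components <= 8   # capped at n - 1

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(4)
        maps = _maps_from_rows(rng.normal(size=(4, 216)), (6, 6, 6))
        with pytest.raises(ValueError, match="mask"):
            reduce_features(maps, np.zeros((6, 6, 6), bool), (3, 3, 3))

    def test_transform_matches_fit_scores(self):
        rng = np.random.default_rng(5)
        maps = _maps_from_rows(rng.normal(size=(7, 216)), (6, 6, 6))
        red, scores = reduce_features(maps, np.ones((6, 6, 6), bool), (3, 3, 3))
        again = pm.transform_features(red, maps)
        np.testing.assert_allclose(again, scores, atol=1e-8)


class TestTrainRvr:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        model = train_rvr(X, np.full(15, 6.5))
        np.testing.assert_allclose(pm.predict_age(model, rng.normal(size=(5, 4))),
                                   6.5, atol=1e-6)

    def test_noiseless_linear_target_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = 4.0 + 2.5 * X[:, 0]
        model = train_rvr(X, y)
        np.testing.assert_allclose(pm.predict_age(model, X), y, atol=1e-3)

    def test_fixed_hyperparameters_match_kernel_ridge_oracle(self):
        """No pruning, frozen alpha/beta: posterior mean equals the
        generalized kernel ridge solution."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        y = 1.0 + X[:, 0] + rng.normal(0, 0.5, 20)
        a0, b0 = 0.7, 3.0
        model = train_rvr(X, y, alpha_init=a0, beta_init=b0,
                          update_hyperparams=False)
        Phi = np.hstack([np.ones((20, 1)), X @ X.T])
        m = np.linalg.solve(b0 * Phi.T @ Phi + a0 * np.eye(21), b0 * Phi.T @ y)
        np.testing.assert_allclose(pm.predict_age(model, X), Phi @ m, atol=1e-6)

    def test_sparsity_on_noisy_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        y = X[:, 0] + rng.normal(0, 0.5, 25)
        model = train_rvr(X, y)
        assert model.n_relevance_vectors < 25

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        y = X[:, 1] + rng.normal(0, 0.3, 12)
        m1, m2 = train_rvr(X, y), train_rvr(X, y)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.retained, m2.retained)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            train_rvr(np.ones((2, 2)), np.array([1.0, 2.0]))


class TestPredictAge:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 3))
        y = 8 + X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 0.2, 15)
        return X, y, train_rvr(X, y)

    def test_linearity_under_convex_combination(self, model):
        X, _, m = model
        lam = 0.3
        mix = lam * X[0] + (1 - lam) * X[1]
        p = pm.predict_age(m, np.vstack([X[0], X[1], mix]))
        assert p[2] == pytest.approx(lam * p[0] + (1 - lam) * p[1], abs=1e-9)

    def test_zero_features_give_bias_term(self, model):
        _, _, m = model
        assert pm.predict_age(m, np.zeros((1, 3)))[0] == pytest.approx(m.bias)

    def test_dimension_mismatch_raises(self, model):
        _, _, m = model
        with pytest.raises(ValueError, match="dimension"):
            pm.predict_age(m, np.ones((1, 7)))


class TestBrainAgeResult:
    def test_score_identity_is_enforced(self):
        table = pd.DataFrame({"id": ["a"], "sex": ["female"], "group": ["CTR"],
                              "age": [5.0], "brain_age": [7.0], "score": [1.0]})
        with pytest.raises(ValueError, match="score"):
            BrainAgeResult(table=table, mae=2.0, r=np.nan, n=1)

    def test_uniform_offset_gives_mae_equal_offset(self):
        """BA = CA + 2 for everyone: MAE is exactly 2 and every score +2."""
        ca = np.array([4.0, 9.5, 13.0, 21.0])
        ba = ca + 2.0
        table = pd.DataFrame({"id": list("abcd"), "sex": ["m"] * 4,
                              "group": ["CTR"] * 4, "age": ca,
                              "brain_age": ba, "score": ba - ca})
        res = BrainAgeResult(table=table, mae=float(np.abs(ba - ca).mean()),
                             r=1.0, n=4)
        assert res.mae == 2.0
        assert (res.table["score"] == 2.0).all()

    def test_perfect_prediction_gives_zero_mae(self):
        ca = np.array([4.0, 9.5, 13.0])
        table = pd.DataFrame({"id": list("abc"), "sex": ["f"] * 3,
                              "group": ["CTR"] * 3, "age": ca,
                              "brain_age": ca, "score": ca - ca})
        res = BrainAgeResult(table=table, mae=0.0, r=1.0, n=3)
        assert res.mae == 0.0 and (res.table["score"] == 0).all()


class TestLoocv:
    def test_noiseless_linear_age_signal_recovered(self):
        """Maps whose voxels are a noiseless linear function of age give
        near-perfect LOOCV (MAE < 0.1 y, r > 0.999)."""
        rng = np.random.default_rng(6)
        ages = np.linspace(4, 22, 12)
        pattern = rng.random((6, 6, 6))
        maps = [0.5 + 0.01 * a * pattern for a in ages]
        res = pm.loocv_brainage(maps, _meta(ages), np.ones((6, 6, 6), bool),
                                (3, 3, 3))
        assert res.mae < 0.1
        assert res.r > 0.999
        np.testing.assert_allclose(res.table["score"],
                                   res.table["brain_age"] - res.table["age"],
                                   atol=1e-12)

    def test_age_unrelated_maps_do_no_better_than_fold_mean(self):
        """Leakage guard: with maps independent of age, LOOCV MAE is no
        better than the fold-mean predictor's error."""
        rng = np.random.default_rng(7)
        ages = rng.uniform(4, 22, 14)
        maps = [rng.normal(0.5, 0.1, (6, 6, 6)) for _ in ages]
        res = pm.loocv_brainage(maps, _meta(ages), np.ones((6, 6, 6), bool),
                                (3, 3, 3))
        # LOO fold-mean predictor baseline
        n = len(ages)
        baseline = np.mean([abs(ages[i] - np.delete(ages, i).mean())
                            for i in range(n)])
        assert res.mae > 0.6 * baseline

    def test_global_reduction_flag_runs(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(5, 20, 8)
        pattern = rng.random((6, 6, 6))
        maps = [0.5 + 0.01 * a * pattern + rng.normal(0, 0.01, (6, 6, 6))
                for a in ages]
        res = pm.loocv_brainage(maps, _meta(ages), np.ones((6, 6, 6), bool),
                                (3, 3, 3), refit_reduction_per_fold=False)
        assert res.n == 8 and np.isfinite(res.mae)


class TestApplyTrainedModel:
    def test_test_equals_train_reproduces_fitted_values(self):
        rng = np.random.default_rng(9)
        ages = np.linspace(4, 22, 10)
        pattern = rng.random((6, 6, 6))
        maps = [0.5 + 0.01 * a * pattern for a in ages]
        meta = _meta(ages)
        res, (red, model) = pm.apply_trained_model(
            maps, meta, maps, meta, np.ones((6, 6, 6), bool), (3, 3, 3))
        scores = pm.transform_features(red, maps)
        np.testing.assert_allclose(res.table["brain_age"],
                                   pm.predict_age(model, scores), atol=1e-9)


class TestHumanEquivalentAge:
    @pytest.mark.parametrize("baboon, human", [(4, 14), (22, 77), (5, 17.5)])
    def test_published_age_pairs(self, baboon, human):
        assert pm.human_equivalent_age(baboon) == pytest.approx(human)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            pm.human_equivalent_age(-1.0)
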
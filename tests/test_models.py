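import numpy as np
import pytest

from kinpred import (
    EnvEffect,
    FixtureSpec,
    RegressorConfig,
    StackedModel,
    evaluate_ef,
    load_model,
    make_fixture,
    predict_ef,
    r2_score,
    save_model,
    split_holdout,
    train_ef,
    train_regressor,
)
from kinpred.models import available_backends, predict

FAST_TREES = {"n_estimators": 30}


class TestTrainRegressor:
    def test_fits_noise_free_linear_synthetic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 16))
        y = X[:, :4].sum(axis=1)
        model = train_regressor(X, y, RegressorConfig(backend_params=FAST_TREES, seed=0))
        assert r2_score(y, model.predict(X)) >= 0.95

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(np.ones((1, 3)), np.ones(1))

    def test_nan_inputs_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_regressor(X, np.ones(4))

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            RegressorConfig(backend="deep_cnn")

    def test_weight_doubling_equals_duplication_for_linear(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(scale=0.1, size=40)
        weights = np.ones(40)
        weights[7] = 2.0
        weighted = train_regressor(X, y, RegressorConfig(backend="linear"), weights)
        X_dup = np.vstack([X, X[7:8]])
        y_dup = np.append(y, y[7])
        duplicated = train_regressor(X_dup, y_dup, RegressorConfig(backend="linear"))
        np.testing.assert_allclose(
            weighted.estimator.coef_, duplicated.estimator.coef_, atol=1e-8
        )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            train_regressor(np.ones((3, 2)), np.ones(3), weights=np.zeros(3))

    def test_registry_covers_tree_and_linear_families(self):
        backends = available_backends()
        assert {"extra_trees", "random_forest", "linear", "ridge"} <= set(backends)


class TestPredict:
    def test_memorizing_ensemble_recovers_duplicated_labels(self):
        rng = np.random.default_rng(2)
        X = np.repeat(rng.normal(size=(50, 4)), 3, axis=0)
        y = np.repeat(rng.normal(size=50), 3)
        model = train_regressor(X, y, RegressorConfig(backend_params=FAST_TREES, seed=0))
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_empty_matrix_gives_empty_predictions(self, small_fixture):
        model = train_regressor(
            small_fixture.features[:50], small_fixture.labels[:50],
            RegressorConfig(backend_params=FAST_TREES, seed=0),
        )
        assert model.predict(np.empty((0, model.feature_dim))).size == 0

    def test_purity(self, small_fixture):
        model = train_regressor(
            small_fixture.features[:50], small_fixture.labels[:50],
            RegressorConfig(backend_params=FAST_TREES, seed=0),
        )
        a = model.predict(small_fixture.features[50:60])
        b = model.predict(small_fixture.features[50:60])
        np.testing.assert_array_equal(a, b)

    def test_dim_mismatch_rejected(self, small_fixture):
        model = train_regressor(
            small_fixture.features[:50], small_fixture.labels[:50],
            RegressorConfig(backend_params=FAST_TREES, seed=0),
        )
        with pytest.raises(ValueError):
            predict(model, np.ones((2, model.feature_dim + 1)))


class TestDeterminismAndPersistence:
    def test_same_seed_same_predictions(self, small_fixture):
        cfg = RegressorConfig(backend_params=FAST_TREES, seed=11)
        a = train_regressor(small_fixture.features[:200], small_fixture.labels[:200], cfg)
        b = train_regressor(small_fixture.features[:200], small_fixture.labels[:200], cfg)
        np.testing.assert_array_equal(
            a.predict(small_fixture.features[200:]), b.predict(small_fixture.features[200:])
        )

    def test_save_load_roundtrip_bit_compatible(self, small_fixture, tmp_path):
        model = train_regressor(
            small_fixture.features[:100], small_fixture.labels[:100],
            RegressorConfig(backend_params=FAST_TREES, seed=0),
        )
        before = model.predict(small_fixture.features[100:150])
        path = tmp_path / "model.joblib"
        save_model(model, path)
        restored = load_model(path)
        after = restored.predict(small_fixture.features[100:150])
        assert before.tobytes() == after.tobytes()
        assert restored.feature_dim == model.feature_dim


class TestParameterRecovery:
    def test_extra_trees_test_r2_above_bar(self):
        # labels linear in 8 embedding coordinates + N(0, 0.1): internal
        # regression-sanity bar of 0.7 at n=2000
        fx = make_fixture(FixtureSpec(n_samples=2000, seed=3, noise_sd=0.1))
        train, test = split_holdout(2000, 0.1, seed=0)
        model = train_regressor(
            fx.features[train], fx.labels[train], RegressorConfig(seed=0)
        )
        assert r2_score(fx.labels[test], model.predict(fx.features[test])) > 0.7


def _oracle_stack(pair_dim, b0, b1, b2, plain_value=0.0):
    """Stacked model whose bases are trivial fitted trees; meta set by hand."""
    X = np.ones((2, pair_dim))
    X[1] *= -1.0
    plain = train_regressor(
        X, np.full(2, plain_value), RegressorConfig(backend_params={"n_estimators": 5}, seed=0)
    )
    Xr = np.ones((2, pair_dim + 1))
    Xr[1] *= -1.0
    revised = train_regressor(
        Xr, np.full(2, plain_value), RegressorConfig(backend_params={"n_estimators": 5}, seed=0)
    )
    return StackedModel(plain, revised, b0, b1, b2)


class TestEFStack:
    def test_meta_identity_forms(self):
        stack = _oracle_stack(4, 0.0, 1.0, 0.0, plain_value=2.0)
        np.testing.assert_allclose(predict_ef(stack, np.ones((3, 4)), 7.0), 2.0)
        stack = _oracle_stack(4, 5.0, 0.0, 0.0)
        np.testing.assert_allclose(predict_ef(stack, np.ones((3, 4)), 7.0), 5.0)

    def test_hand_set_linear_form(self):
        # meta (1, 0.5, 0.5) over base outputs 2 and 4 → 1 + 1 + 2 = 4
        stack = _oracle_stack(4, 1.0, 0.5, 0.5)
        stack.base_plain.estimator = _Const(2.0)
        stack.base_revised.estimator = _Const(4.0)
        np.testing.assert_allclose(predict_ef(stack, np.ones((2, 4)), 7.0), 4.0)

    def test_meta_selects_perfect_revised_base(self):
        # every meta sample duplicates a base sample, so the 1-NN
        # condition-aware base reproduces the meta labels exactly while the
        # condition-free base (trained on constant labels) is uninformative;
        # minimum-norm least squares must then pick meta ≈ (0, 0, 1)
        rng = np.random.default_rng(0)
        d = 6
        Xe = np.repeat(rng.normal(size=(40, d)), 2, axis=0)
        ce = np.repeat(rng.uniform(3, 10.5, size=40), 2)
        ye = np.repeat(rng.normal(size=40), 2)
        base_idx, meta_idx = np.arange(0, 80, 2), np.arange(1, 80, 2)
        X0 = rng.normal(size=(30, d))
        y0 = np.zeros(30)
        cfg = RegressorConfig(backend="knn", backend_params={"n_neighbors": 1})
        stack = train_ef(
            (X0, y0), (Xe, ce, ye), cfg, seed=0,
            base_indices=base_idx, meta_indices=meta_idx,
        )
        assert stack.intercept == pytest.approx(0.0, abs=1e-6)
        assert stack.coef_plain == pytest.approx(0.0, abs=1e-6)
        assert stack.coef_revised == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(stack.predict(Xe, ce), ye, atol=1e-6)

    def test_collinear_bases_well_defined(self):
        # identical base predictions: minimum-norm least squares keeps the
        # stacked prediction equal to the common base prediction
        rng = np.random.default_rng(1)
        n, d = 60, 4
        Xe = np.repeat(rng.normal(size=(20, d)), 3, axis=0)
        ce = np.repeat(rng.uniform(3, 10, size=20), 3)
        ye = np.repeat(rng.normal(size=20), 3)
        cfg = RegressorConfig(backend="knn", backend_params={"n_neighbors": 1})
        stack = train_ef((Xe, ye), (Xe, ce, ye), cfg, seed=0)
        common = stack.base_plain.predict(Xe)
        np.testing.assert_allclose(stack.predict(Xe, ce), common, atol=1e-6)

    def test_tiny_meta_split_rejected(self):
        X = np.ones((6, 3))
        with pytest.raises(ValueError):
            train_ef((X, np.arange(6.0)), (X, np.ones(6), np.arange(6.0)), seed=0)

    def test_stacking_dominates_bases_on_env_fixture(self):
        # condition-aware stacking must not lose to either base (Fig-style
        # ordering): averaged over 3 nested-split repeats
        free = make_fixture(FixtureSpec(n_samples=1000, seed=5, embedder_seed=5))
        env = make_fixture(
            FixtureSpec(n_samples=500, seed=6, embedder_seed=5, env_effect=EnvEffect())
        )
        res = evaluate_ef(
            (free.features, free.labels),
            (env.features, env.conditions, env.labels),
            RegressorConfig(backend_params=FAST_TREES, seed=0),
            seed=0,
            repeats=3,
        )
        assert res["ef"] >= max(res["plain"], res["revised"]) - 0.05


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)
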
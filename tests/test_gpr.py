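"""GP engine: kernel closed forms, factorization, oracle equivalence,
hyperparameter recovery, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from traitgpr.gpr import (
    ARDGaussianProcessRegressor,
    Hyperparams,
    factorize,
    kernel_ase,
    load_model,
    predict_direct,
    predict_mean,
    predict_sigma,
    serialize_model,
    train_gpr,
    _kernel_matrix,
)


def _random_instance(rng, n=None, d=None):
    n = n or int(rng.integers(5, 101))
    d = d or int(rng.integers(1, 22))
    X = rng.normal(size=(n, d))
    y = rng.normal(size=n)
    theta = Hyperparams(
        float(rng.uniform(0.5, 3.0)),
        rng.uniform(0.5, 3.0, size=d),
        float(rng.uniform(0.01, 0.5)),
    )
    return X, y, theta


class TestKernel:
    def test_zero_distance_returns_output_variance(self):
        th = Hyperparams(2.0, np.ones(3), 0.0)
        x = np.array([1.0, -2.0, 0.5])
        assert kernel_ase(x, x, th) == 2.0

    def test_unit_case_closed_form(self):
        th = Hyperparams(1.0, np.ones(1), 0.0)
        assert kernel_ase([0.0], [1.0], th) == pytest.approx(math.exp(-0.5), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(float, 4, elements=st.floats(-5, 5)),
        arrays(float, 4, elements=st.floats(-5, 5)),
    )
    def test_symmetry(self, xi, xj):
        th = Hyperparams(1.3, np.array([0.7, 1.0, 2.0, 0.5]), 0.0)
        assert kernel_ase(xi, xj, th) == kernel_ase(xj, xi, th)

    def test_dimension_mismatch(self):
        th = Hyperparams(1.0, np.ones(2), 0.0)
        with pytest.raises(ValueError):
            kernel_ase([0.0], [1.0, 2.0], th)

    def test_gram_matrix_psd(self, rng):
        X, _, theta = _random_instance(rng, n=40)
        K = _kernel_matrix(X, X, theta)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K + theta.sigma_n2 * np.eye(40))
        assert w.min() >= theta.sigma_n2 - 1e-10


class TestFactorize:
    def test_scalar_case(self):
        th = Hyperparams(2.0, np.ones(1), 0.5)
        L, alpha = factorize(np.zeros((1, 1)), np.array([3.0]), th)
        assert L[0, 0] == pytest.approx(math.sqrt(2.5), abs=1e-12)
        assert alpha[0] == pytest.approx(3.0 / 2.5, abs=1e-12)

    def test_residual(self, rng):
        X, y, theta = _random_instance(rng, n=50)
        L, alpha = factorize(X, y, theta)
        K = _kernel_matrix(X, X, theta) + theta.sigma_n2 * np.eye(50)
        assert np.linalg.norm(K @ alpha - y) / np.linalg.norm(y) < 1e-8

    def test_lower_triangular(self, rng):
        X, y, theta = _random_instance(rng, n=20)
        L, _ = factorize(X, y, theta)
        np.testing.assert_array_equal(np.triu(L, k=1), 0.0)


class TestPredictionOracle:
    def test_factorized_equals_direct(self, rng):
        """Cholesky-path posterior == brute-force inversion on random models."""
        for _ in range(20):
            X, y, theta = _random_instance(rng)
            model = ARDGaussianProcessRegressor(
                init=theta, optimize=False, normalize_x=False, center_y=False
            ).fit(X, y)
            Xq = rng.normal(size=(10, X.shape[1]))
            m, s = model.predict(Xq, return_std=True)
            md, sd = predict_direct(X, y, theta, Xq)
            np.testing.assert_allclose(m, md, rtol=1e-8, atol=1e-8)
            np.testing.assert_allclose(s, sd, rtol=1e-8, atol=1e-8)

    def test_scalar_closed_forms(self):
        th = Hyperparams(1.0, np.ones(1), 1.0)
        X, y = np.zeros((1, 1)), np.array([2.0])
        model = ARDGaussianProcessRegressor(
            init=th, optimize=False, normalize_x=False, center_y=False
        ).fit(X, y)
        m, s = model.predict(np.zeros((1, 1)), return_std=True)
        assert m[0] == pytest.approx(2.0 / 2.0, abs=1e-12)
        assert s[0] ** 2 == pytest.approx(0.5, abs=1e-12)

    def test_noiseless_interpolation(self, rng):
        X, y, _ = _random_instance(rng, n=12, d=3)
        theta = Hyperparams(1.5, np.full(3, 1.2), 0.0)
        model = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, center_y=False
        ).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-7)

    def test_prior_reversion_far_away(self):
        th = Hyperparams(2.5, np.ones(2), 0.1)
        X = np.zeros((4, 2))
        X[:, 0] = [0, 1, 2, 3]
        model = ARDGaussianProcessRegressor(
            init=th, optimize=False, normalize_x=False, center_y=False
        ).fit(X, np.ones(4))
        s = predict_sigma(model, np.full(2, 1e4))
        assert s[0] ** 2 == pytest.approx(2.5, abs=1e-10)

    def test_variance_bounded_by_prior_and_monotone_information(self, rng):
        """Latent variance never exceeds sigma_s2, and adding a training
        point at the query reduces it."""
        X, y, theta = _random_instance(rng, n=30, d=4)
        xq = rng.normal(size=4)
        model = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, center_y=False
        ).fit(X, y)
        s0 = predict_sigma(model, xq)[0]
        assert s0 ** 2 <= theta.sigma_s2 + 1e-12
        X2 = np.vstack([X, xq])
        model2 = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, center_y=False
        ).fit(X2, np.append(y, 0.0))
        assert predict_sigma(model2, xq)[0] <= s0 + 1e-12

    def test_sigma_variants(self, rng):
        X, y, theta = _random_instance(rng, n=15, d=2)
        lat = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, sigma_variant="latent"
        ).fit(X, y)
        obs = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, sigma_variant="observation"
        ).fit(X, y)
        xq = rng.normal(size=(5, 2))
        s_lat = lat.predict(xq, return_std=True)[1]
        s_obs = obs.predict(xq, return_std=True)[1]
        np.testing.assert_allclose(s_obs ** 2 - s_lat ** 2, theta.sigma_n2, atol=1e-10)

    def test_matches_sklearn_fixed_kernel(self, rng):
        """Independent cross-check: sklearn's GP with the same fixed kernel
        produces the same posterior."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        X, y, _ = _random_instance(rng, n=40, d=3)
        theta = Hyperparams(1.7, np.array([0.8, 1.1, 1.4]), 0.2)
        ours = ARDGaussianProcessRegressor(
            init=theta, optimize=False, normalize_x=False, center_y=False
        ).fit(X, y)
        ref = GaussianProcessRegressor(
            kernel=ConstantKernel(1.7, "fixed") * RBF([0.8, 1.1, 1.4], "fixed"),
            alpha=0.2,
            optimizer=None,
        ).fit(X, y)
        Xq = rng.normal(size=(8, 3))
        m_ref, s_ref = ref.predict(Xq, return_std=True)
        m, s = ours.predict(Xq, return_std=True)
        np.testing.assert_allclose(m, m_ref, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(s, s_ref, rtol=1e-6, atol=1e-8)


class TestTraining:
    def test_zero_targets_give_zero_weights(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        model = train_gpr(X, np.zeros(10))
        np.testing.assert_array_equal(model.alpha_, 0.0)
        np.testing.assert_array_equal(model.predict(X), 0.0)

    def test_length_scale_recovery(self, rng):
        """Fit on a GP draw with known hyperparameters; recovered length
        scales within a factor 2 of truth."""
        n, d = 200, 3
        true = Hyperparams(2.0, np.array([0.5, 1.0, 2.0]), 0.01)
        X = rng.uniform(-2, 2, size=(n, d))
        K = _kernel_matrix(X, X, true) + true.sigma_n2 * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.normal(size=n)
        model = ARDGaussianProcessRegressor(
            n_restarts=3, normalize_x=False, center_y=True, random_state=0
        ).fit(X, y)
        ratio = model.theta_.length_scales / true.length_scales
        assert (ratio > 0.5).all() and (ratio < 2.0).all()

    def test_lml_improves_over_init(self, rng):
        X, y, _ = _random_instance(rng, n=60, d=4)
        model = ARDGaussianProcessRegressor(n_restarts=2, random_state=1).fit(X, y)
        Xn = (X - model.input_mean_) / model.input_scale_
        yc = y - model.output_offset_
        init = model._default_init(Xn, yc)
        lml_init, _ = model._lml_and_grad(model._pack(init), Xn, yc)
        assert model.log_marginal_likelihood_ >= lml_init - 1e-9

    def test_duplicated_rows_survive_with_noise(self, rng):
        X = np.repeat(rng.normal(size=(5, 3)), 2, axis=0)
        y = np.repeat(rng.normal(size=5), 2)
        model = train_gpr(X, y, restarts=1)
        assert np.isfinite(model.predict(X)).all()

    @pytest.mark.parametrize(
        "X,y",
        [
            (np.array([[1.0, np.nan]]), np.array([1.0])),
            (np.ones((3, 2)), np.array([1.0, np.inf, 0.0])),
        ],
    )
    def test_nonfinite_rejected(self, X, y):
        with pytest.raises(ValueError):
            train_gpr(np.vstack([X, np.zeros((1, X.shape[1]))]), np.append(y, 0.0))

    def test_sklearn_protocol(self):
        est = ARDGaussianProcessRegressor(n_restarts=2, random_state=7)
        params = est.get_params()
        assert params["n_restarts"] == 2
        cloned = clone(est)
        assert cloned.get_params() == params
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = X[:, 0] ** 2
        assert 0.0 < cloned.fit(X, y).score(X, y) <= 1.0


class TestSerialization:
    def _model(self, rng):
        X, y, _ = _random_instance(rng, n=15, d=4)
        model = train_gpr(X, y, restarts=1, seed=0)
        model.trait_ = "LAI"
        return model

    def test_round_trip_predictions_identical(self, rng):
        model = self._model(rng)
        loaded = load_model(serialize_model(model))
        Xq = rng.normal(size=(6, 4))
        m0, s0 = model.predict(Xq, return_std=True)
        m1, s1 = loaded.predict(Xq, return_std=True)
        np.testing.assert_array_equal(m0, m1)
        np.testing.assert_array_equal(s0, s1)
        assert loaded.trait_ == "LAI"

    def test_json_round_trip(self, rng, tmp_path):
        import json

        doc = serialize_model(self._model(rng))
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        loaded = load_model(json.loads(path.read_text()))
        assert loaded.n_features_in_ == 4

    def test_band_count_mismatch_refused(self, rng):
        doc = serialize_model(self._model(rng))
        doc["band_ids"] = doc["band_ids"][:2]
        with pytest.raises(ValueError, match="band_ids"):
            load_model(doc)

    def test_missing_field_refused(self, rng):
        doc = serialize_model(self._model(rng))
        del doc["alpha"]
        with pytest.raises(ValueError, match="alpha"):
            load_model(doc)

    def test_version_mismatch_refused(self, rng):
        doc = serialize_model(self._model(rng))
        doc["format_version"] = "0.0"
        with pytest.raises(ValueError, match="version"):
            load_model(doc)


def test_predict_mean_sigma_wrappers(rng):
    X, y, theta = _random_instance(rng, n=10, d=2)
    model = ARDGaussianProcessRegressor(init=theta, optimize=False).fit(X, y)
    xq = rng.normal(size=2)
    assert predict_mean(model, xq).shape == (1,)
    assert predict_sigma(model, xq)[0] >= 0
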
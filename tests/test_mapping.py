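"""Scene masking, per-pixel prediction, compositing and CV maps."""

import numpy as np
import pytest

from traitgpr.gpr import ARDGaussianProcessRegressor, Hyperparams
from traitgpr.mapping import (
    Scene,
    TraitMap,
    composite_deviation,
    composite_predict,
    cv_map,
    mask_quality,
    mean_radiance_composite,
    predict_scene,
)
from traitgpr.synth import make_scene


def _small_model(rng, n_bands=5, noise=0.05):
    X = rng.uniform(1.0, 3.0, size=(25, n_bands))
    y = X.sum(axis=1) + rng.normal(0, 0.1, 25)
    theta = Hyperparams(float(y.var()), np.full(n_bands, 2.0), noise)
    m = ARDGaussianProcessRegressor(init=theta, optimize=False).fit(X, y)
    m.trait_ = "toy"
    return m


def _scene(rng, model, h=4, w=4, flags=None):
    B = model.n_features_in_
    radiance = rng.uniform(1.0, 3.0, size=(B, h, w))
    if flags is None:
        flags = np.zeros((h, w), np.uint8)
    return Scene(radiance=radiance, flags=flags)


class TestMaskQuality:
    def test_all_clear(self, rng):
        s = _scene(rng, _small_model(rng))
        assert mask_quality(s).valid.all()

    def test_single_flagged_pixel(self, rng):
        flags = np.zeros((3, 3), np.uint8)
        flags[1, 2] = 0b01  # bright
        s = mask_quality(_scene(rng, _small_model(rng), 3, 3, flags))
        assert not s.valid[1, 2]
        assert s.valid.sum() == 8

    def test_counting_both_bits(self, rng):
        flags = np.zeros((3, 3), np.uint8)
        flags[0, 0] = 0b01
        flags[2, 1] = 0b10  # inland water
        s = mask_quality(_scene(rng, _small_model(rng), 3, 3, flags))
        assert s.valid.sum() == 7

    def test_radiance_untouched(self, rng):
        raw = _scene(rng, _small_model(rng))
        masked = mask_quality(raw)
        np.testing.assert_array_equal(raw.radiance, masked.radiance)

    def test_bit_out_of_range(self, rng):
        with pytest.raises(ValueError):
            mask_quality(_scene(rng, _small_model(rng)), bright_bit=9)


class TestPredictScene:
    def test_constant_scene_constant_map(self, rng):
        model = _small_model(rng)
        vec = rng.uniform(1.0, 3.0, size=model.n_features_in_)
        scene = Scene(
            radiance=np.tile(vec[:, None, None], (1, 3, 3)),
            flags=np.zeros((3, 3), np.uint8),
        )
        tm = predict_scene(model, scene)
        assert np.ptp(tm.mean) == 0.0 and np.ptp(tm.sigma) == 0.0

    def test_vectorized_equals_pixel_loop(self, rng):
        """The batched prediction is numerically identical to per-pixel calls."""
        model = _small_model(rng)
        scene = _scene(rng, model, 8, 8)
        tm = predict_scene(model, scene)
        for i, j in [(0, 0), (3, 5), (7, 7)]:
            m, s = model.predict(scene.radiance[:, i, j][None], return_std=True)
            assert abs(tm.mean[i, j] - m[0]) < 1e-12
            assert abs(tm.sigma[i, j] - s[0]) < 1e-12

    def test_training_spectrum_reproduced_noiseless(self, rng):
        X = rng.uniform(1.0, 3.0, size=(10, 4))
        y = rng.normal(size=10)
        theta = Hyperparams(1.0, np.full(4, 1.5), 0.0)
        model = ARDGaussianProcessRegressor(init=theta, optimize=False).fit(X, y)
        scene = Scene(
            radiance=np.tile(X[3][:, None, None], (1, 2, 2)),
            flags=np.zeros((2, 2), np.uint8),
        )
        tm = predict_scene(model, scene, epsilon=1e-6)
        np.testing.assert_allclose(tm.mean, y[3], atol=1e-6)

    def test_invalid_pixels_are_nodata(self, rng):
        model = _small_model(rng)
        flags = np.zeros((4, 4), np.uint8)
        flags[0, 0] = 1
        scene = mask_quality(_scene(rng, model, 4, 4, flags))
        tm = predict_scene(model, scene)
        assert np.isnan(tm.mean[0, 0]) and not tm.valid_mask[0, 0]

    def test_band_mismatch(self, rng):
        model = _small_model(rng)
        scene = Scene(radiance=rng.uniform(size=(3, 2, 2)), flags=np.zeros((2, 2), np.uint8))
        with pytest.raises(ValueError):
            predict_scene(model, scene)

    def test_crop_commutes(self, rng):
        model = _small_model(rng)
        scene = _scene(rng, model, 6, 6)
        whole = predict_scene(model, scene).crop(slice(1, 4), slice(2, 5))
        from dataclasses import replace

        sub = predict_scene(
            model,
            replace(
                scene,
                radiance=scene.radiance[:, 1:4, 2:5],
                flags=scene.flags[1:4, 2:5],
                valid=scene.valid[1:4, 2:5],
            ),
        )
        np.testing.assert_array_equal(whole.mean, sub.mean)
        np.testing.assert_array_equal(whole.sigma, sub.sigma)


class TestComposites:
    def test_identical_scenes(self, rng):
        model = _small_model(rng)
        s = _scene(rng, model)
        comp = mean_radiance_composite([s, s, s])
        np.testing.assert_allclose(comp.radiance, s.radiance, rtol=1e-15)

    def test_two_scene_mean(self, rng):
        model = _small_model(rng)
        a, b = _scene(rng, model), _scene(rng, model)
        a.radiance[:] = 1.0
        b.radiance[:] = 3.0
        np.testing.assert_array_equal(mean_radiance_composite([a, b]).radiance, 2.0)

    def test_masked_observation_excluded(self, rng):
        model = _small_model(rng)
        a, b = _scene(rng, model, 2, 2), _scene(rng, model, 2, 2)
        a.radiance[:] = 1.0
        b.radiance[:] = 3.0
        b.valid = np.array([[False, True], [True, True]])
        comp = mean_radiance_composite([a, b])
        assert comp.radiance[0, 0, 0] == 1.0
        assert comp.radiance[0, 0, 1] == 2.0

    def test_masked_pixels_never_influence(self, rng):
        """Extreme values under the mask change nothing downstream."""
        model = _small_model(rng)
        a = _scene(rng, model, 3, 3)
        b = _scene(rng, model, 3, 3)
        b.valid = np.ones((3, 3), bool)
        b.valid[1, 1] = False
        poisoned = Scene(
            radiance=b.radiance.copy(),
            flags=b.flags,
            valid=b.valid.copy(),
        )
        poisoned.radiance[:, 1, 1] = 1e9
        clean_map = composite_predict(model, [a, b])
        poisoned_map = composite_predict(model, [a, poisoned])
        np.testing.assert_array_equal(clean_map.mean, poisoned_map.mean)

    def test_single_scene_modes_agree(self, rng):
        model = _small_model(rng)
        s = _scene(rng, model)
        m1 = composite_predict(model, [s], mode="mean_radiance")
        m2 = composite_predict(model, [s], mode="mean_prediction")
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-12)

    def test_repeated_scene_modes_agree(self, rng):
        model = _small_model(rng)
        s = _scene(rng, model)
        m1 = composite_predict(model, [s] * 4, mode="mean_radiance")
        m2 = composite_predict(model, [s] * 4, mode="mean_prediction")
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-10)

    def test_heterogeneous_scenes_modes_differ(self, rng):
        model = _small_model(rng)
        scenes = [_scene(rng, model, 5, 5) for _ in range(6)]
        m1 = composite_predict(model, scenes, mode="mean_radiance")
        m2 = composite_predict(model, scenes, mode="mean_prediction")
        dev = composite_deviation(m1, m2, n_points=25, seed=0)
        assert dev["mean_pct"] > 0

    def test_linear_predictor_modes_identical(self, rng):
        """With a linear test-double predictor the two composite modes agree
        exactly — GP nonlinearity is the only source of deviation."""

        class LinearModel:
            n_features_in_ = 5
            y_min_, y_max_ = 0.0, 1.0
            trait_ = "linear"
            w = np.arange(1.0, 6.0)

            def predict(self, X, return_std=False):
                m = X @ self.w
                return (m, np.zeros_like(m)) if return_std else m

        model = LinearModel()
        scenes = [_scene(rng, _small_model(rng), 4, 4) for _ in range(5)]
        m1 = composite_predict(model, scenes, mode="mean_radiance")
        m2 = composite_predict(model, scenes, mode="mean_prediction")
        np.testing.assert_allclose(m1.mean, m2.mean, rtol=1e-12)

    def test_empty_scene_list(self):
        with pytest.raises(ValueError):
            mean_radiance_composite([])


class TestCompositeDeviation:
    def _map(self, vals):
        vals = np.asarray(vals, float)
        return TraitMap(
            mean=vals,
            sigma=np.zeros_like(vals),
            cv=np.zeros_like(vals),
            valid_mask=np.isfinite(vals),
        )

    def test_identical_maps_zero(self):
        m = self._map([[1.0, 2.0], [3.0, 4.0]])
        assert composite_deviation(m, m)["mean_pct"] == 0.0

    def test_single_pixel_ten_percent(self):
        a = self._map([[1.0]])
        b = self._map([[0.9]])
        assert composite_deviation(a, b)["mean_pct"] == pytest.approx(10.0)

    def test_no_joint_valid(self):
        a = self._map([[np.nan]])
        with pytest.raises(ValueError):
            composite_deviation(a, a)


class TestCVMap:
    def _map(self, mean, sigma):
        mean = np.asarray(mean, float)
        return TraitMap(
            mean=mean,
            sigma=np.asarray(sigma, float),
            cv=np.full_like(mean, np.nan),
            valid_mask=np.isfinite(mean),
        )

    def test_basic_ratio(self):
        tm = cv_map(self._map([[2.0]], [[0.5]]), epsilon=0.01)
        assert tm.cv[0, 0] == pytest.approx(25.0)

    def test_below_epsilon_nodata(self):
        tm = cv_map(self._map([[0.005]], [[0.5]]), epsilon=0.01)
        assert np.isnan(tm.cv[0, 0])

    def test_zero_sigma_zero_cv(self):
        tm = cv_map(self._map([[2.0]], [[0.0]]), epsilon=0.01)
        assert tm.cv[0, 0] == 0.0

    def test_epsilon_validation(self):
        with pytest.raises(ValueError):
            cv_map(self._map([[1.0]], [[0.1]]), epsilon=0.0)


class TestMakeScene:
    def test_cloud_free(self):
        s = make_scene({"LAI": np.full((4, 4), 2.0)}, cloud_fraction=0.0, seed=1)
        assert (s.flags == 0).all()

    def test_exact_cloud_count(self):
        s = make_scene({"LAI": np.full((10, 10), 2.0)}, cloud_fraction=0.25, seed=1)
        assert ((s.flags >> 0) & 1).sum() == 25

    def test_constant_fields_constant_cube(self):
        s = make_scene(
            {"LAI": np.full((3, 3), 2.0), "LCC": np.full((3, 3), 40.0)}, seed=2
        )
        assert s.radiance.shape == (21, 3, 3)
        for b in range(21):
            assert np.ptp(s.radiance[b]) == 0.0

    def test_water_mask_bit(self):
        water = np.zeros((3, 3), bool)
        water[0, 0] = True
        s = make_scene({"LAI": np.full((3, 3), 1.0)}, water_mask=water, seed=0)
        assert (s.flags[0, 0] >> 1) & 1
        masked = mask_quality(s)
        assert not masked.valid[0, 0]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            make_scene({"LAI": np.ones((2, 2)), "LCC": np.ones((3, 3))})
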
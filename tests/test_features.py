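import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermostage.features import (EucDistFeatures, HOGConfig, PCAFeatures,
                                  build_extractor, contour_features,
                                  feature_matrix, hog_features, lbp_features,
                                  stat_features)


def brute_force_hog_length(h, w, cell, block, orientations):
    """Independent block counter: enumerate every block placement."""
    cells_r, cells_c = h // cell, w // cell
    count = 0
    for r in range(cells_r):
        for c in range(cells_c):
            if r + block <= cells_r and c + block <= cells_c:
                count += block * block * orientations
    return count


class TestHOG:
    def test_reference_roi_yields_432_features(self):
        rng = np.random.default_rng(0)
        img = rng.random((210, 240))
        assert hog_features(img).length == 432

    def test_constant_image_gives_zero_vector(self):
        vec = hog_features(np.full((210, 240), 0.4)).values
        assert vec.shape == (432,)
        np.testing.assert_array_equal(vec, 0.0)

    def test_96x96_image_gives_36_features(self):
        img = np.random.default_rng(1).random((96, 96))
        assert hog_features(img).length == 36

    def test_too_small_image_raises_with_minimum(self):
        with pytest.raises(ValueError, match="96"):
            hog_features(np.zeros((90, 240)))

    def test_deterministic(self):
        img = np.random.default_rng(2).random((210, 240))
        np.testing.assert_array_equal(hog_features(img).values,
                                      hog_features(img).values)

    @settings(max_examples=40, deadline=None)
    @given(
        h=st.integers(96, 400), w=st.integers(96, 400),
        cell=st.sampled_from([16, 24, 32, 48]),
        orientations=st.integers(4, 12),
    )
    def test_dimensionality_formula_matches_brute_force(self, h, w, cell, orientations):
        cfg = HOGConfig(cell_size=cell, orientations=orientations)
        if min(h, w) // cell < cfg.block_size:
            return
        assert cfg.n_features(h, w) == brute_force_hog_length(
            h, w, cell, cfg.block_size, orientations
        )

    def test_formula_agrees_with_extractor_output(self):
        img = np.random.default_rng(3).random((150, 200))
        cfg = HOGConfig(cell_size=32)
        assert hog_features(img, cfg).length == cfg.n_features(150, 200)


class TestStat:
    def test_constant_image_guards_higher_moments(self):
        v = stat_features(np.full((50, 50), 0.5)).values
        mean, var, skew, kurt = v[:4]
        assert mean == pytest.approx(0.5)
        assert var == 0.0 and skew == 0.0 and kurt == 0.0

    def test_uniform_noise_moments(self):
        img = np.random.default_rng(5).random((210, 240))
        v = stat_features(img).values
        n = img.size
        assert v[0] == pytest.approx(0.5, abs=3 * np.sqrt(1 / 12 / n))
        # var(sample variance) of U(0,1) ~ 1/180n
        assert v[1] == pytest.approx(1 / 12, abs=3 * np.sqrt(1 / 180 / n))

    def test_symmetric_two_point_image_has_zero_skew(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        assert stat_features(img).values[2] == pytest.approx(0.0)

    def test_length_is_8(self):
        assert stat_features(np.random.default_rng(0).random((30, 30))).length == 8


class TestContour:
    def test_rectangle_geometry(self):
        img = np.zeros((200, 200))
        img[75:125, 50:150] = 1.0  # 50 x 100 filled rectangle
        v = contour_features(img).values
        perimeter, area = v[0], v[1]
        assert area == pytest.approx(5000, rel=0.01)
        assert perimeter == pytest.approx(300, rel=0.02)

    def test_disc_isoperimetric_ratio(self):
        rows, cols = np.mgrid[0:200, 0:200]
        img = (((rows - 100) ** 2 + (cols - 100) ** 2) < 60**2).astype(float)
        v = contour_features(img).values
        assert v[2] == pytest.approx(1 / (4 * np.pi), rel=0.05)

    def test_flat_image_gives_zero_vector(self):
        np.testing.assert_array_equal(contour_features(np.zeros((50, 50))).values,
                                      np.zeros(5))


class TestLBP:
    def test_histogram_sums_to_one(self):
        img = np.random.default_rng(6).random((60, 60))
        assert lbp_features(img).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_image_all_flat_bin(self):
        v = lbp_features(np.full((40, 40), 0.7)).values
        assert v[8] == pytest.approx(1.0)

    def test_rotation_invariance(self):
        img = np.random.default_rng(7).random((64, 64))
        np.testing.assert_allclose(
            lbp_features(img).values, lbp_features(np.rot90(img)).values, atol=1e-12
        )


class TestPCA:
    def _images(self, n, rng):
        return [rng.random((210, 240)) for _ in range(n)]

    def test_flattened_length_is_50400(self):
        assert np.prod((210, 240)) == 50400

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(8)
        imgs = self._images(12, rng)
        pca = PCAFeatures(k=5).fit(imgs)
        v = pca.transform(pca.mean_image.reshape(210, 240)).values
        np.testing.assert_allclose(v, 0.0, atol=1e-8)

    def test_reconstruction_error_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        imgs = self._images(15, rng)
        errs = [PCAFeatures(k=k).fit(imgs).reconstruction_error(imgs)
                for k in (1, 3, 6, 10)]
        assert np.all(np.diff(errs) <= 1e-10)

    def test_k_capped_at_n_minus_one(self):
        rng = np.random.default_rng(10)
        imgs = self._images(5, rng)
        pca = PCAFeatures(k=40).fit(imgs)
        assert pca.transform(imgs[0]).length == 4


class TestEucDist:
    def test_image_equal_to_template_has_zero_minimum(self):
        rng = np.random.default_rng(11)
        imgs = [rng.random((20, 20)) for _ in range(4)]
        ed = EucDistFeatures().fit(imgs, [0, 1, 2, 3])
        v = ed.transform(imgs[2]).values
        assert v[2] == pytest.approx(0.0)
        assert np.argmin(v) == 2
        assert np.all(v >= 0)

    def test_missing_stage_gets_sentinel(self):
        rng = np.random.default_rng(12)
        imgs = [rng.random((20, 20)) for _ in range(3)]
        ed = EucDistFeatures().fit(imgs, [0, 1, 2])
        v = ed.transform(imgs[0]).values
        assert v[3] == np.finfo(float).max

    def test_distance_scales_with_difference(self):
        rng = np.random.default_rng(13)
        base = rng.random((20, 20))
        ed = EucDistFeatures().fit([base, base], [0, 1])
        d1 = ed.transform(base + 0.1).values[0]
        d2 = ed.transform(base + 0.2).values[0]
        assert d2 == pytest.approx(2 * d1)


def test_every_extractor_deterministic_and_finite(tiny_rois):
    rois, stages = tiny_rois
    for method in ("hog", "lbp", "stat", "cont", "pca", "eucdist"):
        ex = build_extractor(method, train_images=rois, train_stages=stages)
        X1 = feature_matrix(rois[:4], ex)
        X2 = feature_matrix(rois[:4], ex)
        np.testing.assert_array_equal(X1, X2)
        assert np.all(np.isfinite(X1))
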
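"""GLCM texture properties, moments, and assembled feature vectors."""

import numpy as np
import pytest

from tfmra import (Segment, cooccurrence, curvelet_feature_vector,
                   dwt1d_baseline_features, dwt2, fdct_wrapping,
                   glcm_features, glcm_properties, moment_features,
                   select_subbands, tf_to_image, wavelet_feature_vector)

from conftest import FS


def brute_force_glcm_props(matrix, n_gray, offset):
    """Literal double-sum evaluation of the four texture formulas."""
    img = tf_to_image(matrix, n_gray)
    rows, cols = img.shape
    dy, dx = offset
    p = np.zeros((n_gray, n_gray))
    for i in range(rows):
        for j in range(cols):
            a, b = i + dy, j + dx
            if 0 <= a < rows and 0 <= b < cols:
                p[img[i, j], img[a, b]] += 1
                p[img[a, b], img[i, j]] += 1  # symmetric accumulation
    p /= p.sum()
    contrast = sum(abs(k - l) ** 2 * p[k, l]
                   for k in range(n_gray) for l in range(n_gray))
    energy = sum(p[k, l] ** 2
                 for k in range(n_gray) for l in range(n_gray))
    homogeneity = sum(p[k, l] / (1 + abs(k - l))
                      for k in range(n_gray) for l in range(n_gray))
    mu_k = sum(k * p[k, l] for k in range(n_gray) for l in range(n_gray))
    mu_l = sum(l * p[k, l] for k in range(n_gray) for l in range(n_gray))
    sig_k = np.sqrt(sum((k - mu_k) ** 2 * p[k, l]
                        for k in range(n_gray) for l in range(n_gray)))
    sig_l = np.sqrt(sum((l - mu_l) ** 2 * p[k, l]
                        for k in range(n_gray) for l in range(n_gray)))
    correlation = sum((k - mu_k) * (l - mu_l) * p[k, l]
                      for k in range(n_gray)
                      for l in range(n_gray)) / (sig_k * sig_l)
    return contrast, correlation, energy, homogeneity


class TestGlcmFeatures:
    def test_constant_matrix_degenerate_values(self):
        assert glcm_features(np.full((6, 6), 3.0)) == (0.0, 1.0, 1.0, 1.0)

    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(50):
            mat = rng.standard_normal((6, 6))
            got = glcm_features(mat, n_gray_levels=4, offsets=((0, 1),))
            want = brute_force_glcm_props(mat, 4, (0, 1))
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_checkerboard_closed_form(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        c, r, e, h = glcm_features(board.astype(float), n_gray_levels=2,
                                   offsets=((0, 1),))
        assert c == pytest.approx(1.0)
        assert e == pytest.approx(0.5)
        assert h == pytest.approx(0.5)
        assert r == pytest.approx(-1.0)

    def test_ranges_on_random_inputs(self, rng):
        for _ in range(20):
            mat = rng.standard_normal((12, 12)) * rng.uniform(0.1, 100)
            c, r, e, h = glcm_features(mat)
            assert c >= 0
            assert -1 <= r <= 1
            assert 0 <= e <= 1
            assert 0 < h <= 1

    def test_transpose_with_mirrored_offset(self, rng):
        img = tf_to_image(rng.standard_normal((10, 10)), 8)
        a = cooccurrence(img, 8, (0, 1))
        b = cooccurrence(img.T, 8, (1, 0))
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_matches_skimage_graycomatrix(self, rng):
        """Independent cross-check of the co-occurrence counting."""
        from skimage.feature import graycomatrix

        img = tf_to_image(rng.standard_normal((16, 16)), 8).astype(np.uint8)
        mine = cooccurrence(img, 8, (0, 1), symmetric=True)
        ref = graycomatrix(img, distances=[1], angles=[0], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(mine, ref, atol=1e-15)


class TestMomentFeatures:
    def test_constant_matrix(self):
        mean, var, skew, kurt = moment_features(np.full((4, 4), 2.5))
        assert (mean, var, skew, kurt) == (2.5, 0.0, 0.0, 0.0)

    def test_symmetric_values_zero_skewness(self):
        mat = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert moment_features(mat)[2] == pytest.approx(0.0)

    def test_normal_sample_kurtosis_near_3(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        assert moment_features(x.reshape(200, 500))[3] == \
            pytest.approx(3.0, abs=0.1)

    def test_matches_direct_formulas(self, rng):
        x = rng.standard_normal((8, 9))
        mean, var, skew, kurt = moment_features(x)
        f = x.ravel()
        assert mean == pytest.approx(f.mean(), abs=1e-12)
        assert var == pytest.approx(((f - f.mean()) ** 2).mean(), abs=1e-12)
        assert skew == pytest.approx(
            ((f - f.mean()) ** 3).mean() / f.std() ** 3, abs=1e-12)
        assert kurt == pytest.approx(
            ((f - f.mean()) ** 4).mean() / f.std() ** 4, abs=1e-12)


@pytest.fixture(scope="module")
def curvelet_bands():
    rng = np.random.default_rng(3)
    return select_subbands(fdct_wrapping(rng.standard_normal((64, 64))))


class TestFeatureVectors:
    def test_curvelet_vector_is_176(self, curvelet_bands):
        fv = curvelet_feature_vector(curvelet_bands)
        assert len(fv.values) == 176
        assert len(fv.names) == 176

    def test_block_structure(self, curvelet_bands):
        fv = curvelet_feature_vector(curvelet_bands)
        suffixes = [n.rsplit("_", 1)[1] for n in fv.names[:8]]
        assert suffixes == ["contrast", "correlation", "energy",
                            "homogeneity", "mean", "variance", "skewness",
                            "kurtosis"]

    def test_deterministic(self, curvelet_bands):
        a = curvelet_feature_vector(curvelet_bands)
        b = curvelet_feature_vector(curvelet_bands)
        assert np.array_equal(a.values, b.values)

    def test_wrong_count_rejected(self, curvelet_bands):
        with pytest.raises(ValueError, match="22"):
            curvelet_feature_vector(curvelet_bands[:-1])

    def test_wavelet_vector_is_104(self, rng):
        fv = wavelet_feature_vector(dwt2(rng.standard_normal((64, 64)), 4))
        assert len(fv.values) == 104
        assert fv.names[0] == "approx_contrast"

    def test_wavelet_constant_image(self):
        fv = wavelet_feature_vector(dwt2(np.full((64, 64), 5.0), 4))
        contrast = [v for v, n in zip(fv.values, fv.names)
                    if n.endswith("_contrast")]
        energy = [v for v, n in zip(fv.values, fv.names)
                  if n.endswith("_energy")]
        assert all(v == 0.0 for v in contrast)
        assert all(v == 1.0 for v in energy)

    def test_shift_robustness_of_curvelet_features(self):
        """A 2-pixel time shift of a TF blob perturbs the feature vector
        only mildly (coarse-scale stability)."""
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        blob = np.exp(-((yy - 30) ** 2 / 50 + (xx - 30) ** 2 / 200))
        shifted = np.exp(-((yy - 30) ** 2 / 50 + (xx - 32) ** 2 / 200))
        a = curvelet_feature_vector(select_subbands(fdct_wrapping(blob)))
        b = curvelet_feature_vector(select_subbands(fdct_wrapping(shifted)))
        rel = np.linalg.norm(a.values - b.values) / np.linalg.norm(a.values)
        assert rel < 0.10


class TestDwt1dBaseline:
    def test_vector_is_18(self, rng):
        seg = Segment(rng.standard_normal(256), FS, 1.0)
        fv = dwt1d_baseline_features(seg)
        assert len(fv.values) == 18

    def test_zero_signal_all_zero(self):
        fv = dwt1d_baseline_features(Segment(np.zeros(256), FS, 1.0))
        np.testing.assert_array_equal(fv.values, 0.0)

    def test_average_power_matches_direct_sum(self, rng):
        import pywt

        seg = Segment(rng.standard_normal(256), FS, 1.0)
        fv = dwt1d_baseline_features(seg)
        coeffs = pywt.wavedec(seg.samples, "db4", mode="periodization",
                              level=5)
        for band_idx, c in enumerate(coeffs):
            direct = sum(v * v for v in c) / len(c)
            assert fv.values[3 * band_idx] == pytest.approx(direct,
                                                            abs=1e-12)

    def test_too_short_rejected(self):
        seg = Segment(np.zeros(16), 64.0, 0.25)
        with pytest.raises(ValueError, match="too short"):
            dwt1d_baseline_features(seg, levels=5)
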
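"""GLCM construction, Haralick features and sliding-window texture images."""

import numpy as np
import pytest
from scipy import ndimage

from fusionfield.core import RasterGrid
from fusionfield.texture import (FEATURE_NAMES, glcm, haralick_features,
                                 plot_texture_means, quantize, texture_image)
from shapely.geometry import box


def brute_glcm(window, offsets, symmetric, n_levels):
    """Pair enumeration with explicit loops (independent of the package)."""
    counts = np.zeros((n_levels, n_levels))
    H, W = window.shape
    for dy, dx in offsets:
        for y in range(H):
            for x in range(W):
                yy, xx = y + dy, x + dx
                if 0 <= yy < H and 0 <= xx < W \
                        and window[y, x] >= 0 and window[yy, xx] >= 0:
                    counts[window[y, x], window[yy, xx]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_features(p):
    """Double-sum evaluation of all eight features, straight from the
    definitions."""
    G = p.shape[0]
    energy = entropy = inertia = idm = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i, j]
            energy += v * v
            if v > 0:
                entropy -= v * np.log2(v)
            inertia += (i - j) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
    px = [sum(p[i, j] for j in range(G)) for i in range(G)]
    py = [sum(p[i, j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(G))
    corr = shade = prom = sum_ijp = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i, j]
            sum_ijp += i * j * v
            d = (i - mu_x) + (j - mu_y)
            shade += d ** 3 * v
            prom += d ** 4 * v
            if var_x > 1e-12 and var_y > 1e-12:
                corr += (i - mu_x) * (j - mu_y) * v / np.sqrt(var_x * var_y)
    mu_t = np.mean(px)
    var_t = np.mean([(r - mu_t) ** 2 for r in px])
    hcorr = (sum_ijp - mu_t ** 2) / var_t if var_t > 1e-12 else 0.0
    return {"energy": energy, "entropy": entropy, "correlation": corr,
            "inverse_difference_moment": idm, "inertia": inertia,
            "cluster_shade": shade, "cluster_prominence": prom,
            "haralick_correlation": hcorr}


class TestQuantize:
    def test_known_bins(self):
        out = quantize(np.array([[0.0, 0.26], [0.99, 1.0]]), 4, (0.0, 1.0))
        assert out.tolist() == [[0, 1], [3, 3]]

    def test_range_max_maps_to_top_level_not_beyond(self):
        assert quantize(np.array([[1.0]]), 8, (0.0, 1.0))[0, 0] == 7

    def test_constant_raster_warns_single_level(self):
        with pytest.warns(UserWarning):
            out = quantize(np.full((3, 3), 0.5), 8)
        assert (out == 0).all()

    def test_nodata_preserved(self):
        out = quantize(np.array([[np.nan, 0.5]]), 4, (0, 1))
        assert out[0, 0] == -1 and out[0, 1] == 2


class TestGLCM:
    def test_checkerboard_symmetric(self):
        m = glcm(np.array([[0, 1], [1, 0]]), [(0, 1)], symmetric=True)
        assert m.p[0, 1] == 0.5 and m.p[1, 0] == 0.5
        assert m.p[0, 0] == 0.0

    def test_constant_window_single_entry(self):
        m = glcm(np.full((3, 3), 2), [(0, 1)], n_levels=4)
        assert m.p[2, 2] == 1.0

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            w = rng.integers(0, 6, (5, 7))
            m = glcm(w, [(0, 1), (1, 0)], symmetric=True, n_levels=6)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_valid_pair_errors(self):
        with pytest.raises(ValueError):
            glcm(np.array([[0, -1], [-1, -1]]), [(0, 1)], n_levels=2)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(10):
            w = rng.integers(-1, 5, (6, 6))
            if (w >= 0).sum() < 4:
                continue
            m = glcm(w, [(0, 1)], symmetric=True, n_levels=5)
            np.testing.assert_allclose(
                m.p, brute_glcm(w, [(0, 1)], True, 5), atol=1e-12)


class TestHaralickFeatures:
    def test_constant_window_degenerate_values(self):
        with pytest.warns(UserWarning):
            f = haralick_features(glcm(np.full((4, 4), 1), [(0, 1)],
                                       n_levels=4))
        assert f.energy == 1.0 and f.entropy == pytest.approx(0.0)
        assert f.inertia == 0.0 and f.inverse_difference_moment == 1.0
        assert f.cluster_shade == 0.0 and f.cluster_prominence == 0.0

    def test_checkerboard_hand_values(self):
        f = haralick_features(glcm(np.array([[0, 1], [1, 0]]), [(0, 1)],
                                   symmetric=True))
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(1.0)       # one bit
        assert f.inertia == pytest.approx(1.0)
        assert f.inverse_difference_moment == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    def test_matches_bruteforce_double_sum(self, rng):
        for _ in range(30):
            w = rng.integers(0, 6, (6, 6))
            m = glcm(w, [(0, 1)], symmetric=True, n_levels=6)
            got = haralick_features(m).to_dict()
            want = brute_features(m.p)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_two_haralick_correlation_conventions_differ(self, rng):
        w = rng.integers(0, 8, (8, 8))
        m = glcm(w, [(0, 1)], symmetric=True, n_levels=8)
        a = haralick_features(m, haralick_corr="marginal_sums")
        b = haralick_features(m, haralick_corr="f3")
        assert a.haralick_correlation != pytest.approx(b.haralick_correlation)
        assert b.haralick_correlation == pytest.approx(a.correlation)

    def test_matches_skimage_for_shared_features(self, rng):
        from skimage.feature import graycomatrix, graycoprops
        for _ in range(10):
            w = rng.integers(0, 8, (9, 9)).astype(np.uint8)
            P = graycomatrix(w, [1], [0], levels=8, symmetric=True,
                             normed=True)
            f = haralick_features(glcm(w.astype(int), [(0, 1)],
                                       symmetric=True, n_levels=8))
            assert f.energy == pytest.approx(
                graycoprops(P, "ASM")[0, 0], abs=1e-8)
            assert f.inertia == pytest.approx(
                graycoprops(P, "contrast")[0, 0], abs=1e-8)
            assert f.correlation == pytest.approx(
                graycoprops(P, "correlation")[0, 0], abs=1e-8)
            assert f.inverse_difference_moment == pytest.approx(
                graycoprops(P, "homogeneity")[0, 0], abs=1e-8)


class TestTextureImage:
    def test_constant_raster_energy_one(self):
        r = RasterGrid(0, 0, 1, np.full((6, 6), 0.3))
        with pytest.warns(UserWarning):
            feats = texture_image(r, radius=1, n_levels=4)
        assert np.allclose(feats["energy"].values, 1.0)

    def test_geometry_passthrough(self, rng):
        r = RasterGrid(3.2, 7.1, 0.045, rng.random((8, 9)))
        feats = texture_image(r, radius=2, n_levels=4)
        for g in feats.values():
            assert g.same_geometry(r)

    def test_matches_per_window_glcm(self, rng):
        r = RasterGrid(0, 0, 1, rng.random((9, 11)))
        feats = texture_image(r, radius=2, n_levels=4)
        q = quantize(r, 4)
        for (y, x) in [(0, 0), (4, 5), (8, 10), (2, 9)]:
            win = q[max(0, y - 2):y + 3, max(0, x - 2):x + 3]
            want = haralick_features(glcm(win, [(0, 1)], symmetric=True,
                                          n_levels=4)).to_dict()
            for name in FEATURE_NAMES:
                assert feats[name].values[y, x] == pytest.approx(
                    want[name], abs=1e-10), (name, y, x)

    def test_nodata_pixels_excluded_and_nan(self, rng):
        vals = rng.random((7, 7))
        vals[3, 3] = np.nan
        feats = texture_image(RasterGrid(0, 0, 1, vals), radius=1, n_levels=4)
        assert np.isnan(feats["entropy"].values[3, 3])
        assert np.isfinite(feats["entropy"].values[0, 0])

    def test_white_noise_has_higher_entropy_than_smoothed(self, rng):
        noise = rng.random((40, 40))
        smooth = ndimage.uniform_filter(noise, 5)
        e_noise = texture_image(RasterGrid(0, 0, 1, noise), radius=2,
                                n_levels=8)["entropy"].values.mean()
        e_smooth = texture_image(RasterGrid(0, 0, 1, smooth), radius=2,
                                 n_levels=8)["entropy"].values.mean()
        assert e_noise > e_smooth

    def test_tiny_raster_errors(self):
        with pytest.raises(ValueError):
            texture_image(RasterGrid(0, 0, 1, np.zeros((1, 1))))


class TestPlotTextureMeans:
    def test_constant_and_half_half(self):
        g1 = RasterGrid(0, 0, 0.1, np.full((10, 10), 1.0))
        feats = {name: g1 for name in FEATURE_NAMES}
        tv = plot_texture_means(feats, box(0, 0, 1, 1))
        assert tv.energy == 1.0
        g2 = RasterGrid(0, 0, 0.1, np.r_[np.full((5, 10), 0.2),
                                         np.full((5, 10), 0.6)])
        tv2 = plot_texture_means({n: g2 for n in FEATURE_NAMES},
                                 box(0, 0, 1, 1))
        assert tv2.entropy == pytest.approx(0.4)
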
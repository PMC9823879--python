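import math

import numpy as np
import pytest

from sczscreen.handcrafted_features import (
    GLCM_NAMES,
    N_UNIFORM_BINS,
    GLCMFeatures,
    LBPHistogram,
    assemble_hf,
    compute_glcm_descriptors,
    glcm_features,
    hf_feature_names,
    lbp_code,
    lbp_histogram,
    lbp_weighted_image,
    quantize,
    uniform_bin_of_code,
)
from sczscreen.preprocess import GrayImage

# offsets used by the 4 standard directions at distance 1 (row, col)
ANGLE_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]


def oracle_glcm(image, mask, levels, offset):
    """Pair-enumeration oracle: explicit loops, symmetrized, normalized."""
    q = quantize(image, levels)
    h, w = q.shape
    M = np.zeros((levels, levels))
    dy, dx = offset
    for y in range(h):
        for x in range(w):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[y, x] and mask[ny, nx]:
                M[q[y, x], q[ny, nx]] += 1
                M[q[ny, nx], q[y, x]] += 1
    return M / M.sum() if M.sum() else None


def oracle_descriptors(P):
    """Independent loop-based descriptor computation (same definitions)."""
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    psum = [0.0] * (2 * n - 1)
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]

    def ent(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    d = {}
    d["contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(n) for j in range(n))
    if sd_x > 0 and sd_y > 0:
        d["correlation"] = sum(
            (i - mu_x) * (j - mu_y) * P[i][j] for i in range(n) for j in range(n)
        ) / (sd_x * sd_y)
    else:
        d["correlation"] = 1.0
    d["energy"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    d["homogeneity"] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    d["entropy"] = ent(P.ravel())
    d["dissimilarity"] = sum(abs(i - j) * P[i][j] for i in range(n) for j in range(n))
    d["maximum_probability"] = max(P.ravel())
    sa = sum(k * psum[k] for k in range(2 * n - 1))
    d["sum_average"] = sa
    d["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(2 * n - 1))
    d["sum_entropy"] = ent(psum)
    dm = sum(k * pdiff[k] for k in range(n))
    d["difference_variance"] = sum((k - dm) ** 2 * pdiff[k] for k in range(n))
    d["difference_entropy"] = ent(pdiff)
    d["autocorrelation"] = sum(i * j * P[i][j] for i in range(n) for j in range(n))
    d["cluster_shade"] = sum(
        (i + j - mu_x - mu_y) ** 3 * P[i][j] for i in range(n) for j in range(n)
    )
    d["cluster_prominence"] = sum(
        (i + j - mu_x - mu_y) ** 4 * P[i][j] for i in range(n) for j in range(n)
    )
    d["inverse_difference"] = sum(P[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    d["inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / n**2) for i in range(n) for j in range(n)
    )
    d["inverse_difference_normalized"] = sum(
        P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
    )
    hx, hy, hxy = ent(px), ent(py), ent(P.ravel())
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0 and P[i][j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(n) for j in range(n)])
    d["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    d["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    d["variance"] = sd_x**2
    d["mean"] = mu_x
    d["joint_max_row_mean"] = sum(max(P[i]) for i in range(n)) / n
    d["trace"] = sum(P[i][i] for i in range(n))
    d["marginal_uniformity"] = sum(p**2 for p in px)
    return np.array([d[name] for name in GLCM_NAMES])


class TestGLCM:
    def test_constant_image(self):
        f = glcm_features(np.full((6, 6), 100.0), np.ones((6, 6), bool))
        named = dict(zip(GLCM_NAMES, f.values))
        assert named["energy"] == 1.0
        assert named["contrast"] == 0.0
        assert named["entropy"] == 0.0

    def test_two_by_two_toy_contrast(self):
        # 2 levels, horizontal pairs only: P = [[0, .5], [.5, 0]] -> contrast 1
        img = np.array([[0.0, 200.0], [0.0, 200.0]])
        f = glcm_features(img, np.ones((2, 2), bool), levels=2, angles=[0.0])
        named = dict(zip(GLCM_NAMES, f.values))
        assert named["contrast"] == pytest.approx(1.0, abs=1e-12)
        assert named["maximum_probability"] == pytest.approx(0.5, abs=1e-12)
        assert named["trace"] == pytest.approx(0.0, abs=1e-12)

    def test_vector_length_and_finiteness(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        f = glcm_features(img, np.ones((16, 16), bool))
        assert f.values.shape == (25,)
        assert np.all(np.isfinite(f.values))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (4, 4))
        mask = rng.random((4, 4)) > 0.2
        angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
        expect, used = np.zeros(25), 0
        for off in ANGLE_OFFSETS:
            P = oracle_glcm(img, mask, 8, off)
            if P is not None:
                expect += oracle_descriptors(P)
                used += 1
        if used == 0:
            pytest.skip("mask too sparse for pairs")
        got = glcm_features(img, mask, levels=8, angles=angles)
        np.testing.assert_allclose(got.values, expect / used, atol=1e-10)

    def test_too_few_pixels_raises(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestLBPCode:
    def test_all_neighbors_equal_center_codes_255(self):
        assert lbp_code(100, [100] * 8) == 255  # ties count as 1

    def test_alternating_neighbors_code_85(self):
        code = lbp_code(100, [110, 90, 110, 90, 110, 90, 110, 90])
        assert code == 85  # bits 01010101 -> 2^0 + 2^2 + 2^4 + 2^6

    def test_shift_invariance_of_plain_rule(self, rng):
        for _ in range(20):
            c = rng.uniform(0, 200)
            nb = rng.uniform(0, 200, 8)
            assert lbp_code(c, nb) == lbp_code(c + 50, nb + 50)


class TestWeightedLBP:
    def test_constant_image_single_spike(self):
        img = GrayImage(np.full((10, 10), 80.0))
        codes, valid = lbp_weighted_image(img, 1)
        hist = lbp_histogram(codes, valid, weight=1, normalize=False)
        assert hist.bins.sum() == valid.sum()
        assert (hist.bins > 0).sum() == 1

    def test_global_weighted_gray_level_arithmetic(self):
        # half 80, half 120: mu = 100, sigma = 20 -> W=2 threshold uses 240,
        # which exceeds every intensity, so no neighbor passes: all codes 0
        img = np.zeros((10, 10))
        img[:, :5] = 80.0
        img[:, 5:] = 120.0
        g = GrayImage(img)
        assert float(img.mean()) == 100.0 and float(img.std()) == 20.0
        codes, valid = lbp_weighted_image(g, 2)
        assert np.all(codes[valid] == 0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bit_count_monotone_in_weight(self, seed):
        rng = np.random.default_rng(seed)
        img = GrayImage(rng.uniform(0, 255, (24, 24)))
        popcounts = []
        for w in (1, 2, 3, 4):
            codes, valid = lbp_weighted_image(img, w)
            popcounts.append(np.unpackbits(codes[valid][:, None], axis=1).sum(axis=1))
        for a, b in zip(popcounts, popcounts[1:]):
            assert np.all(b <= a)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            lbp_weighted_image(GrayImage(np.zeros((5, 5))), 5)


class TestLBPHistogram:
    def test_extreme_codes_are_uniform(self):
        assert uniform_bin_of_code(0) < 58
        assert uniform_bin_of_code(255) < 58

    def test_alternating_code_pools_to_nonuniform_bin(self):
        assert uniform_bin_of_code(85) == 58  # 8 transitions

    def test_58_uniform_patterns_total(self):
        uniform = [c for c in range(256) if uniform_bin_of_code(c) < 58]
        assert len(uniform) == 58

    def test_count_conservation(self, rng):
        codes = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        valid = rng.random((12, 12)) > 0.3
        h = lbp_histogram(codes, valid, normalize=False)
        assert h.bins.sum() == valid.sum()
        assert h.bins.shape == (59,)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            lbp_histogram(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestAssembleHF:
    def _components(self):
        wm = GLCMFeatures(np.arange(25.0), "wm")
        gm = GLCMFeatures(np.arange(25.0) + 100, "gm")
        hists = [LBPHistogram(np.full(59, w / 59), w) for w in (1, 2, 3, 4)]
        return wm, gm, hists

    def test_length_286_and_unique_names(self):
        wm, gm, hists = self._components()
        block = assemble_hf(wm, gm, hists)
        assert block.values.shape == (286,)
        assert len(block.names) == 286
        assert len(set(block.names)) == 286

    def test_order_contract_enforced(self):
        wm, gm, hists = self._components()
        with pytest.raises(ValueError, match="out of order"):
            assemble_hf(gm, wm, hists)
        with pytest.raises(ValueError, match="out of order"):
            assemble_hf(wm, gm, hists[::-1])

    def test_zero_in_zero_out(self):
        block = assemble_hf(
            GLCMFeatures(np.zeros(25), "wm"),
            GLCMFeatures(np.zeros(25), "gm"),
            [LBPHistogram(np.zeros(59), w) for w in (1, 2, 3, 4)],
        )
        assert np.all(block.values == 0)
        assert block.values.shape == (286,)

    def test_segment_order_is_wm_gm_then_lbp(self):
        wm, gm, hists = self._components()
        block = assemble_hf(wm, gm, hists)
        assert np.array_equal(block.values[:25], wm.values)
        assert np.array_equal(block.values[25:50], gm.values)
        assert block.names[0].startswith("glcm_wm")
        assert block.names[50].startswith("lbp_w1")
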
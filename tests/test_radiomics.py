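"""Radiomic extraction: preprocessing, filters, shape and texture."""

import numpy as np
import pytest

from qradbrain.radiomics import (
    FEATURE_CLASSES,
    FeatureDescriptor,
    OFFSETS_13,
    UnsupportedFeatureError,
    _entropy,
    discretize_fbn,
    extract_features,
    feature_manifest,
    first_order_stats,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    log_filter,
    sphericity,
    texture_stats,
    wavelet_subbands,
    zscore_normalize,
)


# ---------------------------------------------------------------------------
# naive triple-loop oracles (independent of the vectorized implementation)

def naive_glcm(labels, mask, n_levels):
    P = np.zeros((n_levels, n_levels))
    idx = np.argwhere(mask)
    mask_set = {tuple(v) for v in idx}
    for v in idx:
        for off in OFFSETS_13:
            w = tuple(v + np.array(off))
            if w in mask_set:
                a, b = labels[tuple(v)] - 1, labels[w] - 1
                P[a, b] += 1
                P[b, a] += 1
    return P / P.sum() if P.sum() else P


def naive_glrlm(labels, mask, n_levels, max_len):
    R = np.zeros((n_levels, max_len))
    shape = labels.shape
    for off in OFFSETS_13:
        off = np.array(off)
        seen = set()
        for v in np.argwhere(mask):
            prev = v - off
            inb = np.all((prev >= 0) & (prev < shape))
            if inb and mask[tuple(prev)] and \
                    labels[tuple(prev)] == labels[tuple(v)]:
                continue  # not a run start
            length = 1
            cur = v.copy()
            while True:
                nxt = cur + off
                if not np.all((nxt >= 0) & (nxt < shape)):
                    break
                if not mask[tuple(nxt)] or \
                        labels[tuple(nxt)] != labels[tuple(v)]:
                    break
                length += 1
                cur = nxt
            key = (tuple(off), tuple(v))
            assert key not in seen
            seen.add(key)
            R[labels[tuple(v)] - 1, length - 1] += 1
    return R


def naive_glszm(labels, mask, n_levels, max_size):
    Z = np.zeros((n_levels, max_size))
    visited = np.zeros(mask.shape, dtype=bool)
    neigh = [np.array(d) for d in np.ndindex(3, 3, 3)]
    neigh = [d - 1 for d in neigh if not np.all(d == 1)]
    for v in np.argwhere(mask):
        if visited[tuple(v)]:
            continue
        g = labels[tuple(v)]
        stack, size = [v], 0
        visited[tuple(v)] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in neigh:
                w = cur + d
                if np.all((w >= 0) & (w < np.array(mask.shape))):
                    tw = tuple(w)
                    if mask[tw] and not visited[tw] and labels[tw] == g:
                        visited[tw] = True
                        stack.append(w)
        Z[g - 1, size - 1] += 1
    return Z


class TestPreprocessing:
    def test_zscore_moments_and_invariances(self, rng):
        img = rng.standard_normal((8, 8, 8)) * 3 + 5
        mask = rng.random((8, 8, 8)) > 0.4
        out = zscore_normalize(img, mask)
        assert out[mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[mask].std() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(zscore_normalize(img + 7.0, mask), out, atol=1e-10)
        assert np.allclose(zscore_normalize(img * 2 + 3, mask), out,
                           atol=1e-10)

    def test_zscore_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_normalize(np.ones((4, 4, 4)), np.ones((4, 4, 4), bool))

    def test_fbn_uniform_occupancy(self, rng):
        img = rng.random((40, 40, 40))
        mask = np.ones(img.shape, bool)
        labels = discretize_fbn(img, mask, 32)
        occ = np.bincount(labels[mask], minlength=33)[1:] / mask.sum()
        assert np.max(np.abs(occ - 1 / 32)) < 0.005

    def test_fbn_boundaries_and_binary(self):
        img = np.zeros((2, 2, 2))
        img[0, 0, 0] = 1.0
        mask = np.ones(img.shape, bool)
        labels = discretize_fbn(img, mask, 2)
        assert labels[0, 0, 0] == 2
        assert set(np.unique(labels)) == {1, 2}

    def test_fbn_constant_image_maps_to_bin_one(self):
        labels = discretize_fbn(np.full((3, 3, 3), 4.2),
                                np.ones((3, 3, 3), bool), 32)
        assert np.all(labels == 1)


class TestFilters:
    def test_log_constant_and_ramp_zero(self):
        assert np.allclose(log_filter(np.ones((10, 10, 10))), 0.0, atol=1e-5)
        ramp = np.tile(np.arange(20.0), (20, 20, 1))
        resp = log_filter(ramp)[5:15, 5:15, 5:15]  # interior only
        assert np.max(np.abs(resp)) < 1e-4

    def test_log_gaussian_blob_closed_form(self):
        # LoG of amplitude-1 Gaussian blob of scale s at the center:
        # -3 * (s^2 / (s^2 + sigma^2))^(3/2) / (s^2 + sigma^2)
        s = 3.0
        g = np.mgrid[:41, :41, :41].astype(float)
        r2 = sum((g[i] - 20.0) ** 2 for i in range(3))
        blob = np.exp(-r2 / (2 * s * s))
        for sigma in (1.0, 2.0):
            t2 = s * s + sigma * sigma
            expected = -3.0 * (s * s / t2) ** 1.5 / t2
            resp = log_filter(blob, sigma=sigma)
            assert resp[20, 20, 20] == pytest.approx(expected, rel=0.02)
            assert resp.argmin() == np.ravel_multi_index((20, 20, 20),
                                                         resp.shape)

    def test_wavelet_constant_image(self):
        sb = wavelet_subbands(np.full((8, 8, 8), 3.0))
        for name, arr in sb.items():
            if "H" in name:
                assert np.allclose(arr, 0.0, atol=1e-12)
        assert np.allclose(sb["LLL"], sb["LLL"].flat[0])
        assert sb["LLL"].flat[0] != 0.0

    def test_wavelet_impulse_energy_preserved(self):
        img = np.zeros((8, 8, 8))
        img[3, 4, 2] = 2.0
        sb = wavelet_subbands(img)
        total = sum(float((a**2).sum()) for a in sb.values())
        assert total == pytest.approx(4.0, abs=1e-10)
        assert len(sb) == 8
        assert all(a.shape == img.shape for a in sb.values())

    def test_wavelet_separable_input_factorizes(self, rng):
        # frozen 1-D Haar stationary filters (periodic):
        low = lambda x: (x + np.roll(x, -1)) / 2.0
        high = lambda x: (x - np.roll(x, -1)) / 2.0
        f, g, h = (rng.standard_normal(8) for _ in range(3))
        img = f[:, None, None] * g[None, :, None] * h[None, None, :]
        sb = wavelet_subbands(img)
        for name, arr in sb.items():
            ops = [low if c == "L" else high for c in name]
            expected = (ops[0](f)[:, None, None]
                        * ops[1](g)[None, :, None]
                        * ops[2](h)[None, None, :])
            assert np.allclose(arr, expected, atol=1e-10)


class TestSphericity:
    def test_digital_ball_near_one(self):
        g = np.mgrid[:45, :45, :45].astype(float)
        ball = sum((g[i] - 22.0) ** 2 for i in range(3)) <= 20.0**2
        assert 0.95 <= sphericity(ball) <= 1.0

    def test_rod_monotone_decreasing(self):
        vals = []
        for k in (6, 12, 24):
            rod = np.zeros((3, 3, 28), bool)
            rod[1, 1, 1:1 + k] = True
            vals.append(sphericity(rod))
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.6

    def test_isotropic_spacing_invariance(self):
        g = np.mgrid[:25, :25, :25].astype(float)
        ball = sum((g[i] - 12.0) ** 2 for i in range(3)) <= 100.0
        assert sphericity(ball, (1, 1, 1)) == pytest.approx(
            sphericity(ball, (2, 2, 2)), abs=1e-6)

    def test_bounded_for_random_masks(self, rng):
        from scipy.ndimage import binary_dilation

        for _ in range(10):
            m = np.zeros((12, 12, 12), bool)
            pts = rng.integers(2, 10, size=(int(rng.integers(3, 30)), 3))
            m[tuple(pts.T)] = True
            m = binary_dilation(m)
            assert sphericity(m) <= 1.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sphericity(np.zeros((5, 5, 5), bool))


class TestTextureMatrices:
    def test_two_voxel_hand_enumeration(self):
        labels = np.ones((3, 3, 3), dtype=int)
        labels[1, 1, 2] = 2
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        P = glcm_matrix(labels, mask, 2)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        stats = texture_stats(labels, mask, 2)
        assert stats["glcm_contrast"] == pytest.approx(1.0)

    def test_degenerate_constant_region(self):
        labels = np.ones((5, 5, 5), dtype=int)
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        stats = texture_stats(labels, mask, 4)
        assert stats["glcm_contrast"] == 0.0
        assert stats["glcm_cluster_prominence"] == 0.0
        assert stats["glszm_zone_entropy"] == 0.0  # single zone

    def test_checkerboard_has_higher_contrast_than_blurred(self):
        g = np.mgrid[:8, :8, :8]
        board = ((g[0] + g[1] + g[2]) % 2 + 1).astype(int)
        mask = np.ones(board.shape, bool)
        sharp = texture_stats(board, mask, 2)["glcm_contrast"]
        # blur by majority-constant: half the voxels flattened to level 1
        blurred = board.copy()
        blurred[:4] = 1
        soft = texture_stats(blurred, mask, 2)["glcm_contrast"]
        assert sharp > soft

    def test_glcm_symmetric_and_normalized(self, rng):
        labels = rng.integers(1, 5, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        P = glcm_matrix(labels, mask, 4)
        assert np.allclose(P, P.T, atol=1e-12)
        assert P.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matrices_match_naive_oracles(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            labels = r.integers(1, 4, (5, 5, 5))
            mask = r.random((5, 5, 5)) > 0.35
            if mask.sum() < 2:
                continue
            P = glcm_matrix(labels, mask, 3)
            assert np.allclose(P, naive_glcm(labels, mask, 3), atol=1e-8)
            R = glrlm_matrix(labels, mask, 3)
            Rn = naive_glrlm(labels, mask, 3, R.shape[1])
            assert np.allclose(R, Rn, atol=1e-8)
            Z = glszm_matrix(labels, mask, 3)
            Zn = naive_glszm(labels, mask, 3, Z.shape[1])
            assert np.allclose(Z, Zn, atol=1e-8)

    def test_tiny_mask_rejected(self):
        labels = np.ones((3, 3, 3), dtype=int)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="2 voxels"):
            texture_stats(labels, mask, 2)


class TestManifest:
    def test_printed_cardinalities(self):
        manifest = feature_manifest()
        tumor = [d for d in manifest if d.region == "tumor"]
        ring = [d for d in manifest if d.region == "ring"]
        assert len(tumor) == 913
        assert len(ring) == 900
        assert len(manifest) == 1813
        assert len({d.key for d in manifest}) == 1813

    def test_class_sizes(self):
        sizes = {k: len(v) for k, v in FEATURE_CLASSES.items()}
        assert sizes == {"shape": 13, "firstorder": 17, "glcm": 22,
                         "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_cardinality_mismatch_rejected(self):
        bad = {k: list(v) for k, v in FEATURE_CLASSES.items()}
        bad["ngtdm"] = bad["ngtdm"] + ["Extra"]
        with pytest.raises(ValueError, match="ngtdm"):
            feature_manifest(bad)

    def test_shape_restricted_to_tumor_original(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("ring", "original", "shape", "Sphericity")
        with pytest.raises(ValueError):
            FeatureDescriptor("tumor", "wavelet-LLL", "shape", "Sphericity")


class TestExtraction:
    def test_constant_image_degenerate_values(self):
        from qradbrain.synthetic import gen_volume

        sample = gen_volume(-1, shape_irregularity=0.0,
                            texture_heterogeneity=0.0, seed=1)
        feats = extract_features(sample, [
            "tumor_original_firstorder_Variance",
            "tumor_original_glcm_Contrast",
            "tumor_original_glszm_ZoneEntropy",
        ])
        assert feats["tumor_original_firstorder_Variance"] == 0.0
        assert feats["tumor_original_glcm_Contrast"] == 0.0
        assert feats["tumor_original_glszm_ZoneEntropy"] == 0.0

    def test_empty_request_and_determinism(self, small_volume):
        assert extract_features(small_volume, []) == {}
        keys = ["tumor_original_shape_Sphericity",
                "ring_log-sigma-1_glcm_Contrast",
                "tumor_wavelet-HHL_glcm_ClusterProminence",
                "tumor_original_glrlm_RunEntropy"]
        a = extract_features(small_volume, keys)
        b = extract_features(small_volume, keys)
        assert a == b
        assert set(a) == set(keys)

    def test_unsupported_descriptor_raises(self, small_volume):
        with pytest.raises(UnsupportedFeatureError):
            extract_features(small_volume, ["tumor_original_ngtdm_Busyness"])
        with pytest.raises(UnsupportedFeatureError):
            extract_features(small_volume, ["no_such_key"])


def test_entropy_helper_zero_log_zero():
    assert _entropy(np.array([4.0, 0.0, 0.0])) == 0.0
    assert _entropy(np.array([1.0, 1.0])) == pytest.approx(1.0)


def test_first_order_stats_basic(rng):
    img = rng.standard_normal((6, 6, 6))
    mask = np.ones(img.shape, bool)
    st = first_order_stats(img, mask)
    assert st["Mean"] == pytest.approx(img.mean())
    assert st["Variance"] == pytest.approx(img.var())
    assert 0.0 < st["Entropy"] <= np.log2(32)
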
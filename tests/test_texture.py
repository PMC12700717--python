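"""Texture feature extraction: hand examples, brute-force oracle equivalence,
and structural invariants of the 368-feature inventory."""

import numpy as np
import pytest

from sonotx.texture import (FeatureName, extract_all, feature_inventory,
                            glcm_features, global_features, glrlm_features,
                            glszm_features, ngtdm_features, quantize,
                            select_peak_frame, wavelet_decompose)

from oracles import (oracle_glcm_features, oracle_glrlm_features,
                     oracle_glszm_features, oracle_ngtdm_features)


def full(size):
    return np.ones((size, size), dtype=bool)


class TestQuantize:
    def test_equal_width_binning_two_levels(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(img, full(16), ng=2)
        assert (q.levels[img < 128] == 1).all()
        assert (q.levels[img >= 128] == 2).all()

    def test_constant_region_maps_to_level_one(self):
        q = quantize(np.full((4, 4), 7.0), full(4), ng=8)
        assert (q.levels == 1).all()

    def test_hand_binning_four_values(self):
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        q = quantize(img, full(2), ng=4)
        assert q.levels.tolist() == [[1, 2], [3, 4]]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4)), np.zeros((4, 4), bool), ng=4)


class TestGlobal:
    def test_constant_region_degenerate_values(self):
        f = global_features(np.full((4, 4), 3.0), full(4))
        assert f["Variance"] == 0 and f["Skewness"] == 0
        assert f["Entropy"] == 0 and f["Energy"] == 1

    def test_population_moments_closed_form(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = global_features(img, full(2))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)

    def test_skewness_hand_computation(self):
        img = np.array([[1.0, 1.0], [1.0, 5.0]])
        f = global_features(img, full(2))
        # ((1-2)^3*3 + (5-2)^3)/4 / 3^1.5
        assert f["Skewness"] == pytest.approx(24 / 4 / 3**1.5)


class TestGLCM:
    def test_constant_roi_sentinels(self):
        q = quantize(np.full((4, 4), 1.0), full(4), ng=4)
        f = glcm_features(q)
        assert f["Contrast"] == 0
        assert f["MaxProbability"] == 1
        assert f["Correlation"] == 0  # zero-variance sentinel

    def test_two_by_two_single_offset(self):
        img = np.array([[1.0, 2.0], [1.0, 2.0]])
        q = quantize(img, full(2), ng=2)
        f = glcm_features(q, offsets=[(0, 1)])
        # counts {(1,2):2, (2,1):2}; Contrast = 1
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["MaxProbability"] == pytest.approx(0.5)

    def test_checkerboard_axis_offsets_anticorrelated(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
        q = quantize(img, full(8), ng=2)
        f = glcm_features(q, offsets=[(0, 1), (1, 0)])
        assert f["Correlation"] == pytest.approx(-1.0)


class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        img = np.array([[0.0, 0.0, 10.0]])
        q = quantize(img, np.ones((1, 3), bool), ng=2)
        f = glrlm_features(q, directions=[(0, 1)])
        assert f["RP"] == pytest.approx(2 / 3)

    def test_constant_row_run_emphasis(self):
        n = 6
        img = np.full((1, n), 4.0)
        q = quantize(img, np.ones((1, n), bool), ng=2)
        f = glrlm_features(q, directions=[(0, 1)])
        assert f["LRE"] == pytest.approx(n**2)
        assert f["SRE"] == pytest.approx(1 / n**2)

    def test_all_unit_runs_zero_rlv(self):
        img = np.array([[1.0, 2.0, 1.0, 2.0]])
        q = quantize(img, np.ones((1, 4), bool), ng=2)
        f = glrlm_features(q, directions=[(0, 1)])
        assert f["RLV"] == pytest.approx(0.0)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        img = np.full((2, 5), 3.0)
        q = quantize(img, np.ones((2, 5), bool), ng=2)
        f = glszm_features(q)
        assert f["ZP"] == pytest.approx(1 / 10)
        assert f["LZE"] == pytest.approx(100)

    def test_equal_zone_sizes_zero_variance(self):
        img = np.array([[1.0, 2.0]])
        q = quantize(img, np.ones((1, 2), bool), ng=2)
        assert glszm_features(q)["ZSV"] == pytest.approx(0.0)

    def test_three_zone_hand_enumeration(self):
        img = np.array([[10.0, 10.0], [20.0, 30.0]])
        q = quantize(img, full(2), ng=3)
        f = glszm_features(q)
        assert f["ZP"] == pytest.approx(3 / 4)
        assert f["LZHGE"] == pytest.approx(17 / 3)


class TestNGTDM:
    def test_constant_roi_degenerate(self):
        q = quantize(np.full((3, 3), 5.0), full(3), ng=4)
        f = ngtdm_features(q)
        assert f["Busyness"] == 0 and f["Strength"] == 0
        assert f["Coarseness"] == pytest.approx(1.0e6)

    def test_center_spike_matches_neighbor_mean_oracle(self):
        img = np.ones((3, 3))
        img[1, 1] = 2.0
        q = quantize(img, full(3), ng=2)
        got = ngtdm_features(q)
        want = oracle_ngtdm_features(q.levels, q.ng, q.mask)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k

    def test_intensity_doubling_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(10, 50, (6, 6))
        f1 = ngtdm_features(quantize(img, full(6), ng=4))
        f2 = ngtdm_features(quantize(2 * img, full(6), ng=4))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)


class TestOracleEquivalence:
    """All Group-2 features agree with exhaustive enumeration on random ROIs."""

    @pytest.mark.parametrize("seed", range(8))
    def test_group2_matches_enumeration(self, seed):
        from conftest import random_masked_image
        rng = np.random.default_rng(seed)
        img, mask = random_masked_image(rng, size=10, full_mask=(seed % 2 == 0))
        q = quantize(img, mask, ng=4)
        checks = [
            (glcm_features(q), oracle_glcm_features(
                q.levels, q.ng, [(0, 1), (1, 1), (1, 0), (1, -1)])),
            (glrlm_features(q), oracle_glrlm_features(
                q.levels, q.ng, [(0, 1), (1, 0), (1, 1), (1, -1)], q.n_pixels)),
            (glszm_features(q), oracle_glszm_features(q.levels, q.ng, q.n_pixels)),
            (ngtdm_features(q), oracle_ngtdm_features(q.levels, q.ng, q.mask)),
        ]
        for got, want in checks:
            for name, val in want.items():
                assert got[name] == pytest.approx(val, abs=1e-10), name


class TestWavelet:
    def test_constant_image_details_vanish(self):
        bands = wavelet_decompose(np.full((16, 16), 9.0), full(16))
        for name, (band, _) in bands.items():
            if name != "ca2":
                assert np.abs(band).max() < 1e-12
        ca2 = bands["ca2"][0]
        assert np.ptp(ca2) < 1e-12

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (32, 32))
        bands = wavelet_decompose(img, full(32))
        total = sum(float((b**2).sum()) for b, _ in bands.values())
        assert total == pytest.approx(float((img**2).sum()), rel=1e-8)

    def test_horizontal_edge_energy_in_ch(self):
        edge = np.zeros((16, 16))
        edge[5:, :] = 10.0
        bands = wavelet_decompose(edge, full(16))
        assert (bands["ch1"][0] ** 2).sum() > 0
        assert (bands["cv1"][0] ** 2).sum() == pytest.approx(0.0, abs=1e-12)

    def test_indivisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            wavelet_decompose(np.zeros((18, 18)), full(18)[:18, :18])

    def test_mask_decimation_requires_all_parents(self):
        mask = np.ones((8, 8), dtype=bool)
        mask[0, 0] = False
        bands = wavelet_decompose(np.zeros((8, 8)), mask)
        m1 = bands["ch1"][1]
        assert not m1[0, 0] and m1[0, 1]


class TestInventory:
    def test_exactly_368_named_features(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (32, 32))
        feats = extract_all(img, full(32), ng=8)
        assert len(feats) == 368
        names = list(feats)
        assert sum(1 for n in names if n.startswith("Global-")) == 6
        native = [n for n in names if FeatureName.parse(n).subband == "native"]
        assert len(native) == 46

    def test_reported_feature_names_present(self):
        names = {fn.render() for fn in feature_inventory()}
        for quoted in ("ca2-GLRLM-RLV", "cv2-GLSZM-LZHGE", "cv2-GLSZM-LZLGE",
                       "ch2-GLSZM-LGZE", "ch2-GLRLM-LGRE", "ch1-Global-Variance",
                       "ch1-Global-Skewness", "ca2-NGTDM-Strength",
                       "cd1-NGTDM-Coarseness", "cv1-GLSZM-ZSV", "ca2-GLSZM-LZE",
                       "ca2-GLCM-Correlation", "NGTDM-Busyness"):
            assert quoted in names, quoted

    def test_name_round_trip(self):
        for fn in feature_inventory():
            assert FeatureName.parse(fn.render()) == fn

    def test_deterministic_and_shift_scale_invariant_group2(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 200, (16, 16))
        mask = full(16)
        f1 = extract_all(img, mask, ng=8)
        f2 = extract_all(img, mask, ng=8)
        assert f1 == f2
        # affine intensity change before quantization: all native Group-2
        # features unchanged
        f3 = extract_all(3.0 * img + 11.0, mask, ng=8)
        for fn in feature_inventory():
            if fn.subband == "native" and fn.family != "Global":
                name = fn.render()
                assert f1[name] == pytest.approx(f3[name], rel=1e-9), name


def test_peak_frame_is_argmax_of_mean_roi_intensity():
    mask = np.zeros((4, 4), dtype=bool)
    mask[1:3, 1:3] = True
    frames = np.stack([np.full((4, 4), v) for v in (1.0, 5.0, 3.0)])
    assert select_peak_frame(frames, mask) == 1
    assert select_peak_frame(frames[0], mask) == 0
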
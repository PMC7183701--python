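"""Co-occurrence and run-length matrices against brute-force oracles."""

import numpy as np
import pytest

from lnradiomics.features.glcm import glcm, glcm_features, glcm_panel
from lnradiomics.features.glrlm import glrlm, glrlm_features, glrlm_panel
from lnradiomics.synthetic import FIXTURES, fixture_matrix
from lnradiomics.types import QuantizedROI

from oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_glrlm_features,
    brute_runs,
)

DIRECTIONS = (0, 45, 90, 135)


def random_roi(seed, shape=(9, 11), b=8, mask_p=0.8):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, b + 1, size=shape)
    mask = rng.uniform(size=shape) < mask_p
    mask.flat[rng.integers(0, mask.size)] = True  # never empty
    return QuantizedROI(np.where(mask, levels, 0), mask, b)


class TestGLCM:
    def test_two_level_pairs_hand_enumerated(self):
        roi = fixture_matrix("two_level_2x2")
        m = glcm(roi, 0, 1)
        assert np.allclose(m.probabilities, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_single_entry(self):
        roi = fixture_matrix("constant_4x4")
        for d in DIRECTIONS:
            p = glcm(roi, d, 1).probabilities
            assert p[0, 0] == 1.0 and p.sum() == 1.0

    def test_checkerboard_off_diagonal_mass(self):
        roi = fixture_matrix("checker_4x4")
        p = glcm(roi, 0, 1).probabilities
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5
        assert p[0, 0] == 0.0 and p[1, 1] == 0.0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matrix_matches_bruteforce(self, direction, seed):
        roi = random_roi(seed)
        got = glcm(roi, direction, 1).probabilities
        ref = brute_glcm(roi.levels, roi.mask, direction, 1)
        bb = ref.shape[0]
        assert np.allclose(got[:bb, :bb], ref, atol=1e-12)
        assert np.allclose(got[bb:, :], 0.0)

    def test_matrix_is_symmetric_and_normalized(self):
        m = glcm(random_roi(7), 45, 1)
        assert m.symmetric
        assert abs(m.probabilities.sum() - 1.0) < 1e-12

    def test_no_pair_direction_raises(self):
        levels = np.array([[1, 0], [0, 2]])
        mask = levels > 0
        roi = QuantizedROI(levels, mask, 2)
        with pytest.raises(ValueError):
            glcm(roi, 0, 1)  # the two pixels are diagonal neighbours only

    def test_constant_feature_limits(self):
        roi = fixture_matrix("constant_4x4")
        f = glcm_panel(roi)
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["dissimilarity"] == 0.0
        assert f["homogeneity"] == 1.0

    def test_checkerboard_contrast_and_dissimilarity(self):
        roi = fixture_matrix("checker_4x4")
        f = glcm_features([glcm(roi, 0, 1)])
        assert abs(f["contrast"] - 1.0) < 1e-12
        assert abs(f["dissimilarity"] - 1.0) < 1e-12

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_direction_average_equals_bruteforce_mean(self, seed):
        roi = random_roi(seed)
        f = glcm_panel(roi)
        per_dir = [brute_glcm_features(brute_glcm(roi.levels, roi.mask, d, 1))
                   for d in DIRECTIONS]
        for k in f:
            assert abs(f[k] - np.mean([d[k] for d in per_dir])) < 1e-12

    def test_rotation_permutes_directions(self):
        """Rotating 90 deg swaps 0<->90 and 45<->135, leaving averages fixed."""
        roi = random_roi(3, mask_p=1.0)
        rot = QuantizedROI(np.rot90(roi.levels), np.rot90(roi.mask), roi.n_levels)
        pairs = {0: 90, 90: 0, 45: 135, 135: 45}
        for d, d2 in pairs.items():
            a = glcm(roi, d, 1).probabilities
            b = glcm(rot, d2, 1).probabilities
            assert np.allclose(a, b, atol=1e-12)
        fa, fb = glcm_panel(roi), glcm_panel(rot)
        for k in fa:
            assert abs(fa[k] - fb[k]) < 1e-9


class TestGLRLM:
    def test_constant_rows_hand_enumerated(self):
        roi = fixture_matrix("constant_4x4")
        m = glrlm(roi, 0)
        assert m.counts[0, 3] == 4 and m.counts.sum() == 4
        f = glrlm_features([m])
        assert f["rp"] == 0.25
        assert f["lre"] == 16.0

    def test_checkerboard_unit_runs(self):
        roi = fixture_matrix("checker_4x4")
        f = glrlm_features([glrlm(roi, 0)])
        assert f["sre"] == 1.0 and f["lre"] == 1.0 and f["rp"] == 1.0

    def test_two_level_row_and_column_runs(self):
        roi = fixture_matrix("two_level_2x2")
        # rows are the constant runs: 2 runs over 4 pixels
        assert glrlm_features([glrlm(roi, 0)])["rp"] == 0.5
        # columns alternate: 4 unit runs
        assert glrlm_features([glrlm(roi, 90)])["rp"] == 1.0

    def test_mask_truncates_runs(self):
        roi = fixture_matrix("line_mask")  # constant image, one full row
        m = glrlm(roi, 0)
        assert m.counts[0, 3] == 1 and m.counts.sum() == 1
        assert glrlm_features([m])["rp"] == 0.25

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_features_match_bruteforce(self, direction, seed):
        roi = random_roi(seed)
        got = glrlm_features([glrlm(roi, direction)])
        ref = brute_glrlm_features(roi.levels, roi.mask, direction)
        for k in got:
            assert abs(got[k] - ref[k]) < 1e-12, k

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_run_pixel_conservation(self, direction):
        """Run-weighted pixel count equals in-mask pixel count."""
        roi = random_roi(11, shape=(8, 8))
        m = glrlm(roi, direction)
        lengths = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * lengths).sum() == roi.mask.sum()
        runs = brute_runs(roi.levels, roi.mask, direction)
        assert sum(ln for _, ln in runs) == roi.mask.sum()

    def test_fixture_suite_oracle_equivalence(self):
        for name in FIXTURES:
            roi = fixture_matrix(name)
            for d in DIRECTIONS:
                got = glrlm_features([glrlm(roi, d)])
                ref = brute_glrlm_features(roi.levels, roi.mask, d)
                for k in got:
                    assert abs(got[k] - ref[k]) < 1e-12, (name, d, k)


class TestAffineInvariance:
    def test_quantized_features_invariant_under_affine_intensity_map(self):
        from lnradiomics.imaging import normalize_quantize
        from lnradiomics.types import ImageSlice

        rng = np.random.default_rng(5)
        img = rng.normal(60, 8, size=(16, 16))
        mask = np.ones((16, 16), bool)
        r1 = normalize_quantize(ImageSlice(img), mask, 8)
        r2 = normalize_quantize(ImageSlice(3.2 * img + 17.0), mask, 8)
        assert glcm_panel(r1) == glcm_panel(r2)
        assert glrlm_panel(r1) == glrlm_panel(r2)
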
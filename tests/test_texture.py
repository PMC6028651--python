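import numpy as np
import pytest

from oracles import glcm_counts, glcm_feature_formulas, glrlm_counts
from petrad.features import (
    DIRECTIONS_13,
    GLCM,
    GLCM_NAMES,
    GLRLM,
    GLRLM_NAMES,
    compute_glcm,
    compute_glrlm,
    discretize,
    glcm_features,
    glrlm_features,
    texture_features,
)


class TestDiscretize:
    def test_constant_voi_single_level(self):
        levels = discretize(np.full((2, 2, 2), 4.2))
        assert levels.max() == 1
        assert (levels == 1).all()

    def test_floor_rule_hand_values(self):
        vals = np.array([[[0.0, 0.05], [0.1, 0.25]]])
        levels = discretize(vals, bin_width=0.1)
        np.testing.assert_array_equal(levels, [[[1, 1], [2, 3]]])

    def test_shift_invariance(self, rng):
        vals = rng.random((4, 4, 4)) * 3
        np.testing.assert_array_equal(
            discretize(vals), discretize(vals + 17.3)
        )

    def test_only_masked_voxels_assigned(self, rng):
        vals = rng.random((3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        levels = discretize(vals, mask)
        assert (levels[~mask] == 0).all()
        assert (levels[mask] > 0).all()


class TestGLCM:
    def test_constant_2x2x2_single_entry(self):
        glcm = compute_glcm(discretize(np.full((2, 2, 2), 1.0)))
        assert glcm.matrix.shape == (1, 1)
        assert glcm.matrix[0, 0] == 1.0

    def test_axial_hand_enumeration(self):
        # 2x2x1 grid, levels [[1,2],[1,2]]: offsets restricted to axes.
        # (1,0,0): pairs (1,1),(2,2); (0,1,0): pairs (1,2),(1,2).
        # After symmetrization: 8 endpoints total.
        levels = np.array([[[1], [2]], [[1], [2]]])
        glcm = compute_glcm(levels, offsets=[(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        expected = np.array([[2, 2], [2, 2]]) / 8.0
        np.testing.assert_allclose(glcm.matrix, expected)

    def test_symmetric_and_normalized(self, ball_voi):
        glcm = compute_glcm(discretize(ball_voi))
        np.testing.assert_array_equal(glcm.matrix, glcm.matrix.T)
        assert glcm.matrix.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, size=3))
        vals = rng.random(shape)
        mask = rng.random(shape) < 0.7
        mask[tuple(s // 2 for s in shape)] = True
        levels = discretize(vals, mask, bin_width=0.25)
        counts = glcm_counts(levels, DIRECTIONS_13)
        if counts.sum() == 0:
            pytest.skip("no valid pairs in this draw")
        glcm = compute_glcm(levels)
        np.testing.assert_allclose(glcm.matrix, counts / counts.sum(), atol=1e-14)

    def test_no_valid_pairs_is_an_error(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[0, 0, 0] = 1
        levels[2, 2, 2] = 2  # too far apart for distance-1 offsets
        with pytest.raises(ValueError, match="pair"):
            compute_glcm(levels)


class TestGLCMFeatures:
    def test_constant_voi_limits(self):
        feats = glcm_features(compute_glcm(discretize(np.full((2, 2, 2), 2.0))))
        assert feats["contrast"] == 0.0
        assert feats["dissimilarity"] == 0.0
        assert feats["energy_c"] == 1.0
        assert feats["entropy_c"] == 0.0
        assert feats["maximum_probability"] == 1.0
        assert feats["correlation"] == 1.0  # homogeneous limit

    def test_2x2_matrix_matches_formula_oracle(self):
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        feats = glcm_features(GLCM(matrix=p, offsets=((1, 0, 0),)))
        oracle = glcm_feature_formulas(p)
        assert set(feats) == set(oracle)
        for name in feats:
            assert feats[name] == pytest.approx(oracle[name], abs=1e-12), name

    def test_random_glcm_matches_formula_oracle(self, rng):
        raw = rng.random((5, 5))
        p = raw + raw.T
        p /= p.sum()
        feats = glcm_features(GLCM(matrix=p))
        oracle = glcm_feature_formulas(p)
        for name in feats:
            assert feats[name] == pytest.approx(oracle[name], rel=1e-10, abs=1e-12), name

    def test_has_exactly_23_entries(self, ball_voi):
        feats = glcm_features(compute_glcm(discretize(ball_voi)))
        assert list(feats) == GLCM_NAMES
        assert len(feats) == 23


class TestGLRLM:
    def test_single_line_single_run(self):
        levels = np.ones((1, 1, 5), dtype=int)
        glrlm = compute_glrlm(levels, directions=[(0, 0, 1)])
        assert glrlm.n_runs == 1
        assert glrlm.matrix[0, 4] == 1  # one run of length 5

    def test_two_runs_hand_enumeration(self):
        levels = np.array([1, 1, 2, 2, 2]).reshape(1, 1, 5)
        glrlm = compute_glrlm(levels, directions=[(0, 0, 1)])
        assert glrlm.matrix[0, 1] == 1  # level 1, length 2
        assert glrlm.matrix[1, 2] == 1  # level 2, length 3
        assert glrlm.n_runs == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_run_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(2, 7, size=3))
        vals = rng.random(shape)
        mask = rng.random(shape) < 0.8
        mask[tuple(s // 2 for s in shape)] = True
        levels = discretize(vals, mask, bin_width=0.3)
        expected = glrlm_counts(levels, DIRECTIONS_13)
        got = compute_glrlm(levels).matrix
        np.testing.assert_array_equal(got, expected)


class TestGLRLMFeatures:
    def test_single_run_closed_form(self):
        n = 5
        glrlm = compute_glrlm(np.ones((1, 1, n), dtype=int), directions=[(0, 0, 1)])
        feats = glrlm_features(glrlm, n_voxels=n)
        assert feats["sre"] == pytest.approx(1.0 / n**2)
        assert feats["lre"] == pytest.approx(float(n**2))
        assert feats["rp"] == pytest.approx(1.0 / n)

    def test_all_unit_runs(self):
        levels = np.arange(1, 6).reshape(1, 1, 5)  # strictly increasing
        glrlm = compute_glrlm(levels, directions=[(0, 0, 1)])
        feats = glrlm_features(glrlm, n_voxels=5)
        assert feats["sre"] == 1.0
        assert feats["rp"] == 1.0

    def test_has_exactly_11_entries(self, ball_voi):
        levels = discretize(ball_voi)
        feats = glrlm_features(compute_glrlm(levels), n_voxels=int((levels > 0).sum()))
        assert list(feats) == GLRLM_NAMES
        assert len(feats) == 11

    def test_sre_le_one_le_lre(self, rng):
        vals = rng.random((5, 5, 5))
        levels = discretize(vals, bin_width=0.4)
        glrlm = compute_glrlm(levels)
        feats = glrlm_features(glrlm, n_voxels=125)
        assert feats["sre"] <= 1.0 + 1e-12 <= feats["lre"] + 2e-12


def test_texture_total_is_34(ball_voi):
    feats = texture_features(ball_voi)
    assert len(feats) == 34
    assert set(feats) == set(GLCM_NAMES) | set(GLRLM_NAMES)


def test_texture_invariant_to_intensity_shift(ball_voi):
    class Shifted:
        suv = ball_voi.suv + 5.0
        mask = ball_voi.mask

    a = texture_features(ball_voi)
    b = texture_features(Shifted)
    for name in a:
        assert a[name] == pytest.approx(b[name], rel=1e-10), name
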
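"""GLM t-maps, cluster forming, and permutation cluster-level FWE."""

import numpy as np
import pytest
from scipy import stats

from vbasym.asymmetry import AIImage, HemisphereMask
from vbasym.inference import (
    DesignMatrix,
    InferenceParams,
    fit_glm,
    permutation_cluster_fwe,
    threshold_clusters,
    within_group_asymmetry,
)
from vbasym.io_core import make_affine


def _mask(shape=(17, 16, 16)):
    aff = make_affine(shape, 3.0)
    m = np.zeros(shape, dtype=bool)
    m[shape[0] // 2 + 1 :, :, :] = True
    return HemisphereMask(m, aff)


def _ai_from_values(values, mask):
    """One AIImage per subject whose masked voxels all carry that subject's value."""
    out = []
    for i, v in enumerate(np.atleast_1d(values)):
        data = np.where(mask.mask, float(v), 0.0)
        out.append(AIImage(data, mask, subject_id=f"s{i}"))
    return out


def _ai_from_matrix(Y, mask):
    out = []
    for i, row in enumerate(Y):
        data = np.zeros(mask.shape)
        data[mask.mask] = np.clip(row, -2, 2)
        out.append(AIImage(data, mask, subject_id=f"s{i}"))
    return out


class TestFitGLM:
    def test_identical_groups_give_zero_t(self):
        mask = _mask()
        ai = _ai_from_values([0.3] * 6, mask)
        design = DesignMatrix.group_design(["a"] * 3 + ["b"] * 3, {"a": 1, "b": -1})
        tmap = fit_glm(ai, design)
        assert np.all(tmap.data == 0.0)

    def test_two_sample_closed_form(self):
        # A = {0.2, 0.4, 0.3}, B = {-0.1, -0.3, -0.2}: t = 0.5/sqrt(0.01*(2/3)), df = 4
        mask = _mask((3, 2, 2))
        ai = _ai_from_values([0.2, 0.4, 0.3, -0.1, -0.3, -0.2], mask)
        design = DesignMatrix.group_design(["a"] * 3 + ["b"] * 3, {"a": 1, "b": -1})
        tmap = fit_glm(ai, design)
        np.testing.assert_allclose(tmap.masked_values(), 6.123724, rtol=1e-6)
        assert tmap.df == 4

    def test_zero_residual_variance_guard(self):
        mask = _mask((3, 2, 2))
        ai = _ai_from_values([0.5, 0.5, 0.5], mask)
        design = DesignMatrix.one_sample(3)
        tmap = fit_glm(ai, design)
        assert np.all(tmap.data == 0.0)

    def test_matches_scipy_ttest_on_random_fixtures(self):
        mask = _mask((5, 4, 4))
        rng = np.random.default_rng(0)
        nA, nB = 7, 9
        Y = rng.normal(0, 0.3, (nA + nB, mask.n_voxels))
        ai = _ai_from_matrix(Y, mask)
        design = DesignMatrix.group_design(["a"] * nA + ["b"] * nB, {"a": 1, "b": -1})
        tmap = fit_glm(ai, design)
        expected = stats.ttest_ind(Y[:nA], Y[nA:], axis=0, equal_var=True).statistic
        np.testing.assert_allclose(tmap.masked_values(), expected, rtol=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X, ["a", "b"], np.array([1.0, -1.0]))

    def test_design_image_count_mismatch_rejected(self):
        mask = _mask((3, 2, 2))
        ai = _ai_from_values([0.1, 0.2], mask)
        with pytest.raises(ValueError, match="design"):
            fit_glm(ai, DesignMatrix.one_sample(5))


def _brute_force_components(coords, connectivity):
    """Flood-fill oracle for connected components over voxel index tuples."""
    coords = {tuple(c) for c in coords}
    comps = []
    while coords:
        stack = [coords.pop()]
        comp = {stack[0]}
        while stack:
            c = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) > 1:
                            continue
                        nb = (c[0] + dx, c[1] + dy, c[2] + dz)
                        if nb in coords:
                            coords.remove(nb)
                            comp.add(nb)
                            stack.append(nb)
        comps.append(comp)
    return sorted((len(c) for c in comps), reverse=True)


class TestThresholdClusters:
    def test_all_zero_tmap_gives_no_clusters(self):
        mask = _mask()
        ai = _ai_from_values([0.0, 0.0, 0.0, 0.0], mask)
        tmap = fit_glm(ai, DesignMatrix.one_sample(4))
        assert threshold_clusters(tmap, InferenceParams()) == []

    def test_two_blobs_match_flood_fill_oracle(self):
        from vbasym.inference import TMap

        mask = _mask((17, 16, 16))
        tgrid = np.zeros((17, 16, 16))
        blob1 = [(10 + i, 5, 5) for i in range(5)] + [(10, 5 + j, 5) for j in range(1, 6)]
        blob2 = [(13, 9 + j, 10) for j in range(7)]
        for c in blob1 + blob2:
            tgrid[c] = 9.0
        tmap = TMap(tgrid, 10, mask)
        clusters = threshold_clusters(tmap, InferenceParams(connectivity=26))
        sizes = sorted((c["k"] for c in clusters), reverse=True)
        assert sizes == _brute_force_components(blob1 + blob2, 26)

    def test_connectivity_6_vs_26_splits_diagonal_touch(self):
        from vbasym.inference import TMap

        mask = _mask((17, 16, 16))
        tgrid = np.zeros((17, 16, 16))
        # two runs touching only diagonally at (11,5,5)-(12,6,6)
        a = [(11, 5, 5), (11, 4, 5), (10, 5, 5)]
        b = [(12, 6, 6), (12, 7, 6), (13, 6, 6)]
        for c in a + b:
            tgrid[c] = 9.0
        tmap = TMap(tgrid, 10, mask)
        k26 = len(threshold_clusters(tmap, InferenceParams(connectivity=26)))
        k6 = len(threshold_clusters(tmap, InferenceParams(connectivity=6)))
        assert k26 == len(_brute_force_components(a + b, 26)) == 1
        assert k6 == len(_brute_force_components(a + b, 6)) == 2


class TestPermutationFWE:
    def _effect_images(self, rng, n=8, effect=0.5):
        mask = _mask((17, 16, 16))
        Y = rng.normal(0, 0.2, (n, mask.n_voxels))
        grid = np.zeros(mask.shape)
        grid[12:15, 5:9, 5:9] = effect
        Y += grid[mask.mask]
        return _ai_from_matrix(Y, mask), mask

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        ai, _ = self._effect_images(rng)
        design = DesignMatrix.one_sample(len(ai))
        params = InferenceParams(n_permutations=200, seed=42)
        r1 = permutation_cluster_fwe(ai, design, params)
        r2 = permutation_cluster_fwe(ai, design, params)
        assert [(r.k, r.p_fwe) for r in r1] == [(r.k, r.p_fwe) for r in r2]

    def test_effect_detected_with_significant_cluster(self):
        rng = np.random.default_rng(6)
        ai, _ = self._effect_images(rng, n=10, effect=0.6)
        design = DesignMatrix.one_sample(len(ai))
        params = InferenceParams(n_permutations=500, seed=1)
        recs = permutation_cluster_fwe(ai, design, params)
        assert any(r.significant for r in recs)
        top = max(recs, key=lambda r: r.k)
        assert top.p_fwe <= 0.05

    def test_p_monotone_in_cluster_size(self):
        rng = np.random.default_rng(7)
        ai, _ = self._effect_images(rng, n=10, effect=0.4)
        design = DesignMatrix.one_sample(len(ai))
        recs = permutation_cluster_fwe(ai, design, InferenceParams(n_permutations=200, seed=3))
        for a in recs:
            for b in recs:
                if a.k >= b.k:
                    assert a.p_fwe <= b.p_fwe

    def test_addone_estimator_bounds(self):
        rng = np.random.default_rng(8)
        ai, _ = self._effect_images(rng, n=8, effect=0.5)
        design = DesignMatrix.one_sample(len(ai))
        n_perm = 200
        recs = permutation_cluster_fwe(ai, design, InferenceParams(n_permutations=n_perm, seed=3))
        for r in recs:
            assert r.p_fwe >= 1.0 / (1 + n_perm)
            assert r.p_fwe <= 1.0

    def test_exhaustive_enumeration_for_small_n(self, caplog):
        import logging

        rng = np.random.default_rng(9)
        mask = _mask((5, 4, 4))
        Y = rng.normal(0.4, 0.2, (5, mask.n_voxels))
        ai = _ai_from_matrix(Y, mask)
        design = DesignMatrix.one_sample(5)
        with caplog.at_level(logging.INFO, logger="vbasym.inference"):
            recs = permutation_cluster_fwe(ai, design, InferenceParams(n_permutations=100, seed=0))
        assert "exhaustive" in caplog.text
        # 2^5 = 32 distinct sign flips; p-values quantized accordingly
        for r in recs:
            assert abs(r.p_fwe * 33 - round(r.p_fwe * 33)) < 1e-9

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="100"):
            InferenceParams(n_permutations=50)

    def test_group_label_permutation_detects_group_difference(self):
        rng = np.random.default_rng(10)
        mask = _mask((17, 16, 16))
        n = 10
        Y = rng.normal(0, 0.2, (2 * n, mask.n_voxels))
        grid = np.zeros(mask.shape)
        grid[11:15, 4:10, 4:10] = 0.5
        Y[:n] += grid[mask.mask]
        Y[n:] -= grid[mask.mask]
        ai = _ai_from_matrix(Y, mask)
        design = DesignMatrix.group_design(["a"] * n + ["b"] * n, {"a": 1, "b": -1})
        recs = permutation_cluster_fwe(ai, design, InferenceParams(n_permutations=300, seed=2))
        assert any(r.significant for r in recs)


class TestWithinGroupAsymmetry:
    def test_negation_swaps_lists_exactly(self):
        rng = np.random.default_rng(11)
        mask = _mask((17, 16, 16))
        Y = rng.normal(0, 0.2, (8, mask.n_voxels))
        grid = np.zeros(mask.shape)
        grid[12:15, 5:9, 5:9] = 0.6
        Y += grid[mask.mask]
        ai = _ai_from_matrix(Y, mask)
        neg = _ai_from_matrix(-Y, mask)
        params = InferenceParams(n_permutations=150, seed=4)
        lw, rw = within_group_asymmetry(ai, params)
        lw2, rw2 = within_group_asymmetry(neg, params)
        assert [(r.k, r.p_fwe) for r in lw] == [(r.k, r.p_fwe) for r in rw2]
        assert [(r.k, r.p_fwe) for r in rw] == [(r.k, r.p_fwe) for r in lw2]

    def test_leftward_effect_lands_in_leftward_list_only(self):
        rng = np.random.default_rng(12)
        mask = _mask((17, 16, 16))
        Y = rng.normal(0, 0.15, (10, mask.n_voxels))
        grid = np.zeros(mask.shape)
        grid[12:15, 5:9, 5:9] = 0.6
        Y += grid[mask.mask]
        ai = _ai_from_matrix(Y, mask)
        lw, rw = within_group_asymmetry(ai, InferenceParams(n_permutations=300, seed=5))
        assert any(r.significant for r in lw)
        assert not any(r.significant for r in rw)

    def test_all_zero_images_give_empty_lists(self):
        mask = _mask((5, 4, 4))
        ai = _ai_from_values([0.0, 0.0, 0.0, 0.0], mask)
        lw, rw = within_group_asymmetry(ai, InferenceParams(n_permutations=100, seed=6))
        assert lw == [] and rw == []

    def test_fewer_than_three_subjects_rejected(self):
        mask = _mask((5, 4, 4))
        ai = _ai_from_values([0.1, 0.2], mask)
        with pytest.raises(ValueError, match="3"):
            within_group_asymmetry(ai, InferenceParams(n_permutations=100))
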
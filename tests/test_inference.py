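"""Sign-flip permutation inference, TFCE and conjunction."""

import numpy as np
import pytest

from narrisc.dataio import DataError, PValueMap
from narrisc.inference import (PermutationScheme, TFCEParams, conjunction_min,
                               permutation_test, sign_flip_stat, tfce_array)
from narrisc.isc import mean_isc_map, pairwise_within_isc

from conftest import make_cohort


@pytest.fixture
def small_matrix():
    cohort = make_cohort(n_subjects=4, conditions=("a",), shape=(3, 3, 3),
                         T=30, seed=0)
    return pairwise_within_isc(cohort, "a")


class TestSignFlip:
    def test_all_plus_one_equals_mean_map(self, small_matrix):
        m = sign_flip_stat(small_matrix, np.ones(small_matrix.n_pairs))
        np.testing.assert_array_equal(m.data, mean_isc_map(small_matrix).data)

    def test_all_minus_one_negates(self, small_matrix):
        m = sign_flip_stat(small_matrix, -np.ones(small_matrix.n_pairs))
        np.testing.assert_allclose(m.data, -mean_isc_map(small_matrix).data)

    def test_opposite_signs_on_equal_pairs_cancel(self):
        cohort = make_cohort(n_subjects=2, conditions=("a", "b"),
                             shape=(2, 1, 1), T=10, seed=1)
        from narrisc.isc import pairwise_between_isc
        m = pairwise_between_isc(cohort, "a", "b")
        m.values[0, :] = 0.7
        m.values[1, :] = 0.7
        out = sign_flip_stat(m, np.array([1.0, -1.0]))
        np.testing.assert_allclose(out.data[np.isfinite(out.data)], 0.0)


class TestTFCE:
    def test_zero_map_maps_to_zero(self):
        assert np.all(tfce_array(np.zeros((4, 4, 4))) == 0)

    def test_single_voxel_matches_dense_discrete_sum(self):
        """An isolated voxel of height 2 with E=0.5, H=2 integrates to
        sum e^0.5 h^2 dh with e=1, which the dense-step oracle evaluates as
        ~ integral_0^2 h^2 dh = 8/3."""
        grid = np.zeros((5, 5, 5))
        grid[2, 2, 2] = 2.0
        params = TFCEParams(E=0.5, H=2.0, n_steps=100, connectivity=26)
        got = tfce_array(grid, params)[2, 2, 2]

        # dense brute-force oracle at 10^4 steps
        n_dense = 10_000
        dh = 2.0 / n_dense
        oracle = sum((1.0 ** 0.5) * ((k * dh) ** 2) * dh
                     for k in range(1, n_dense + 1))
        assert got == pytest.approx(oracle, rel=0.05)
        assert oracle == pytest.approx(8.0 / 3.0, rel=0.001)

    def test_raising_a_voxel_never_decreases_scores(self):
        """Raising a voxel (without changing the image max, which would move
        the discrete threshold ladder) only grows supra-threshold sets, so no
        voxel's score can drop."""
        rng = np.random.default_rng(2)
        grid = rng.random((4, 4, 4))
        grid[1, 1, 1] = 1.5  # fixed maximum
        base = tfce_array(grid, TFCEParams(n_steps=200))
        for idx in [(0, 0, 0), (2, 2, 2), (3, 1, 0)]:
            raised = grid.copy()
            raised[idx] = min(raised[idx] + 0.4, 1.5)
            out = tfce_array(raised, TFCEParams(n_steps=200))
            assert np.all(out >= base - 1e-9)

    def test_step_doubling_converges(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage
        grid = ndimage.gaussian_filter(rng.standard_normal((8, 8, 8)), 1.5)
        grid = np.clip(grid, 0, None)
        a = tfce_array(grid, TFCEParams(n_steps=200))
        b = tfce_array(grid, TFCEParams(n_steps=400))
        denom = np.abs(a).max()
        assert np.abs(a - b).max() / denom < 0.01

    def test_connectivity_changes_extent(self):
        grid = np.zeros((3, 3, 3))
        grid[0, 0, 0] = grid[1, 1, 1] = 1.0  # diagonal neighbours
        t26 = tfce_array(grid, TFCEParams(connectivity=26, n_steps=50))
        t6 = tfce_array(grid, TFCEParams(connectivity=6, n_steps=50))
        assert t26[0, 0, 0] > t6[0, 0, 0]  # joined cluster has extent 2


class TestPermutationTest:
    def test_constant_positive_matrix_reaches_min_p(self):
        # 8 subjects -> 28 pairs: the chance a sign pattern reproduces the
        # all-positive observed map is 99 * 2^-28, i.e. negligible
        cohort = make_cohort(n_subjects=8, conditions=("a",), shape=(3, 3, 3),
                             T=10, seed=10)
        matrix = pairwise_within_isc(cohort, "a")
        matrix.values[:] = 0.9
        _, pmap = permutation_test(matrix, TFCEParams(n_steps=20),
                                   PermutationScheme(n_perm=99, seed=0))
        inside = np.isfinite(pmap.data)
        np.testing.assert_allclose(pmap.data[inside], 1.0 / 100.0)

    def test_same_seed_reproduces_bit_identically(self, small_matrix):
        args = (TFCEParams(n_steps=20), PermutationScheme(n_perm=49, seed=42))
        obs1, p1 = permutation_test(small_matrix, *args)
        obs2, p2 = permutation_test(small_matrix, *args)
        np.testing.assert_array_equal(p1.data, p2.data)
        np.testing.assert_array_equal(obs1.data, obs2.data)

    def test_p_monotone_in_observed_tfce(self, small_matrix):
        obs, pmap = permutation_test(small_matrix, TFCEParams(n_steps=20),
                                     PermutationScheme(n_perm=99, seed=1))
        inside = np.isfinite(obs.data)
        t = obs.data[inside]
        p = pmap.data[inside]
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_subject_blocks_mode_runs_and_differs(self, small_matrix):
        _, p_ind = permutation_test(small_matrix, TFCEParams(n_steps=20),
                                    PermutationScheme(n_perm=99, seed=2))
        _, p_blk = permutation_test(
            small_matrix, TFCEParams(n_steps=20),
            PermutationScheme(mode="subject_blocks", n_perm=99, seed=2))
        assert p_blk.data.shape == p_ind.data.shape
        assert np.all(p_blk.data[np.isfinite(p_blk.data)] >= 1.0 / 100.0)

    def test_block_signs_flip_pairs_coherently(self, small_matrix):
        """In subject_blocks mode a pair's sign is the product of its two
        subjects' signs, so the product of signs around any 3-cycle of pairs
        (i,j),(j,k),(i,k) is +1."""
        from narrisc.inference import _draw_signs
        rng = np.random.default_rng(3)
        signs = _draw_signs(small_matrix,
                            PermutationScheme(mode="subject_blocks", n_perm=1),
                            rng)
        idx = {(p[0], p[1]): s for p, s in zip(small_matrix.pairs, signs)}
        subs = small_matrix.subjects
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                for k in range(j + 1, len(subs)):
                    cyc = (idx[(subs[i], subs[j])] * idx[(subs[j], subs[k])]
                           * idx[(subs[i], subs[k])])
                    assert cyc == pytest.approx(1.0)


class TestConjunction:
    def _pmap(self, data):
        return PValueMap(data=np.asarray(data, dtype=float), corrected=True,
                         n_perm=99)

    def test_identical_masks_idempotent(self):
        p = np.full((2, 2, 2), 0.2)
        p[0, 0, 0] = 0.01
        out = conjunction_min([self._pmap(p), self._pmap(p)], alpha=0.05)
        assert out.sum() == 1 and out[0, 0, 0]

    def test_disjoint_masks_empty(self):
        a = np.ones((2, 2, 2))
        b = np.ones((2, 2, 2))
        a[0, 0, 0] = 0.01
        b[1, 1, 1] = 0.01
        assert conjunction_min([self._pmap(a), self._pmap(b)]).sum() == 0

    def test_three_maps_equal_elementwise_and(self):
        rng = np.random.default_rng(4)
        maps = [self._pmap(rng.random((3, 3, 3)) * 0.2) for _ in range(3)]
        out = conjunction_min(maps, alpha=0.05)
        expected = np.ones((3, 3, 3), dtype=bool)
        for m in maps:
            expected &= m.data < 0.05
        np.testing.assert_array_equal(out, expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            conjunction_min([self._pmap(np.ones((2, 2, 2))),
                             self._pmap(np.ones((3, 3, 3)))])
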
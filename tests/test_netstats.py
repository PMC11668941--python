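"""Parcel aggregation and spatial permutation tests.

The tiny-atlas tests compare Monte-Carlo p-values against exhaustive
enumeration over every distinct parcel-to-network assignment, which is
feasible for 6 parcels in two 3-parcel networks (C(6,3) = 20).
"""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dbscycle as d
from dbscycle.netstats import network_means, network_suppressions


def exhaustive_one_sided(v, assignment):
    """Exact per-network P(surrogate suppression >= observed) by
    enumerating all distinct assignments (uniform over them)."""
    v = np.asarray(v, float)
    obs = network_suppressions(v, assignment)
    distinct = sorted(set(permutations(assignment.tolist())))
    k = max(assignment)
    counts = np.zeros(k)
    for a in distinct:
        surr = network_suppressions(v, np.array(a))
        counts += surr >= obs
    return counts / len(distinct)


def exhaustive_two_sided(d_vec, assignment):
    d_vec = np.asarray(d_vec, float)
    obs = np.abs(network_means(d_vec, assignment))
    distinct = sorted(set(permutations(assignment.tolist())))
    k = max(assignment)
    counts = np.zeros(k)
    for a in distinct:
        surr = np.abs(network_means(d_vec, np.array(a)))
        counts += surr >= obs
    return counts / len(distinct)


class TestParcelMeans:
    def test_constant_map(self, tiny_atlas):
        vol = np.full(tiny_atlas.labels.shape, 3.5)
        np.testing.assert_allclose(d.parcel_means(vol, tiny_atlas), 3.5)

    def test_map_equal_to_parcel_id(self, tiny_atlas):
        vol = tiny_atlas.labels.astype(float)
        np.testing.assert_allclose(
            d.parcel_means(vol, tiny_atlas), tiny_atlas.parcel_ids
        )

    def test_hand_arithmetic(self, tiny_atlas):
        vol = np.zeros(tiny_atlas.labels.shape)
        vox = np.argwhere(tiny_atlas.labels == 1)
        vol[tuple(vox[0])] = -1.0
        vol[tuple(vox[1])] = -3.0
        # remaining parcel-1 voxels zero: mean = sum/size
        expected = (-1.0 - 3.0) / len(vox)
        assert d.parcel_means(vol, tiny_atlas)[0] == pytest.approx(expected)

    def test_all_nan_parcel_warns(self, tiny_atlas):
        vol = np.zeros(tiny_atlas.labels.shape)
        vol[tiny_atlas.labels == 2] = np.nan
        with pytest.warns(UserWarning):
            out = d.parcel_means(vol, tiny_atlas)
        assert np.isnan(out[1])

    def test_grid_mismatch_rejected(self, tiny_atlas):
        with pytest.raises(ValueError):
            d.parcel_means(np.zeros((2, 2, 2)), tiny_atlas)


class TestNetworkMeans:
    def test_single_network_equals_grand_mean(self):
        v = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(network_means(v, np.array([1, 1, 1])), [3.0])

    def test_hand_example_with_suppression_signs(self):
        v = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        a = np.array([1, 1, 1, 2, 2, 2])
        np.testing.assert_allclose(network_means(v, a), [-1.0, 1.0])
        np.testing.assert_allclose(network_suppressions(v, a), [1.0, -1.0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_joint_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=12)
        a = rng.integers(1, 4, size=12)
        a[:3] = [1, 2, 3]  # every network present
        perm = rng.permutation(12)
        np.testing.assert_allclose(
            network_means(v[perm], a[perm], 3), network_means(v, a, 3)
        )


class TestOneSidedSuppression:
    def test_unbeatable_network_hits_resolution_floor(self, atlas100):
        v = np.where(atlas100.assignment == 7, -1.0, 0.0)
        res = d.one_sided_suppression_test(v, atlas100.assignment, n_perm=10_000,
                                           seed=3)
        assert res.p_uncorrected[6] == 1.0 / 10_000
        assert res.p_bonferroni[6] == pytest.approx(7.0 / 10_000)

    def test_constant_vector_is_never_significant(self, atlas100):
        res = d.one_sided_suppression_test(
            np.full(100, -2.0), atlas100.assignment, n_perm=200, seed=0
        )
        np.testing.assert_array_equal(res.p_uncorrected, 1.0)

    def test_fixed_seed_reproduces_everything(self, atlas100):
        v = np.random.default_rng(8).normal(size=100)
        a = d.one_sided_suppression_test(v, atlas100.assignment, n_perm=500, seed=4)
        b = d.one_sided_suppression_test(v, atlas100.assignment, n_perm=500, seed=4)
        np.testing.assert_array_equal(a.p_uncorrected, b.p_uncorrected)
        np.testing.assert_array_equal(a.surrogate_mean, b.surrogate_mean)

    def test_matches_exhaustive_enumeration(self, tiny_atlas):
        v = np.array([-2.0, -1.0, -3.0, 0.0, 1.0, 2.0])
        exact = exhaustive_one_sided(v, tiny_atlas.assignment)
        n_perm = 10_000
        res = d.one_sided_suppression_test(v, tiny_atlas.assignment, n_perm=n_perm,
                                           seed=21)
        mc = res.n_beyond / n_perm
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert np.all(np.abs(mc - exact) <= 2 * se + 1e-12)

    def test_result_table_has_expected_columns(self, tiny_atlas):
        res = d.one_sided_suppression_test(
            np.arange(6.0), tiny_atlas.assignment, n_perm=50, seed=0
        )
        frame = res.to_frame()
        for col in ("network", "observed", "p_uncorrected", "p_bonferroni",
                    "surrogate_mean", "surrogate_sd", "n_perm", "seed"):
            assert col in frame.columns


class TestTwoSidedDifference:
    def test_identical_vectors_give_p_one(self, tiny_atlas):
        v = np.arange(6.0)
        res = d.two_sided_difference_test(v, v, tiny_atlas.assignment, n_perm=100,
                                          seed=0)
        np.testing.assert_array_equal(res.p_uncorrected, 1.0)

    def test_sign_flip_leaves_p_unchanged(self, tiny_atlas):
        rng = np.random.default_rng(11)
        va, vb = rng.normal(size=6), rng.normal(size=6)
        res1 = d.two_sided_difference_test(va, vb, tiny_atlas.assignment,
                                           n_perm=2000, seed=5)
        res2 = d.two_sided_difference_test(vb, va, tiny_atlas.assignment,
                                           n_perm=2000, seed=5)
        np.testing.assert_array_equal(res1.p_uncorrected, res2.p_uncorrected)

    def test_matches_exhaustive_enumeration(self, tiny_atlas):
        va = np.array([-2.0, -1.0, -3.0, 0.0, 1.0, 2.0])
        vb = np.zeros(6)
        exact = exhaustive_two_sided(va - vb, tiny_atlas.assignment)
        n_perm = 10_000
        res = d.two_sided_difference_test(va, vb, tiny_atlas.assignment,
                                          n_perm=n_perm, seed=13)
        mc = res.n_beyond / n_perm
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert np.all(np.abs(mc - exact) <= 2 * se + 1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 7, 0.07), (0.5, 7, 1.0), (0.3, 1, 0.3), (0.0, 7, 0.0)],
    )
    def test_examples(self, p, m, expected):
        assert d.bonferroni_adjust(np.array([p]), m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            d.bonferroni_adjust(np.array([1.5]), 7)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000), m=st.integers(1, 20))
    def test_bounds_and_monotonicity(self, seed, m):
        p = np.sort(np.random.default_rng(seed).uniform(0, 1, 10))
        adj = d.bonferroni_adjust(p, m)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert np.all(np.diff(adj) >= 0)


class TestNullCalibration:
    def test_false_positive_rate_near_nominal(self, atlas100):
        """Uncorrected one-sided p < 0.05 occurs for ~5% of networks
        across i.i.d. noise parcel vectors."""
        rng = np.random.default_rng(2024)
        n_perm = 1000
        hits = total = 0
        for _ in range(300):
            v = rng.normal(size=100)
            res = d.one_sided_suppression_test(
                v, atlas100.assignment, n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            hits += int((res.p_uncorrected < 0.05).sum())
            total += 7
        rate = hits / total
        assert 0.03 <= rate <= 0.07
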
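import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfqt import (
    SimConfig,
    doubly_ranked_deciles,
    doubly_ranked_strata,
    naive_strata,
    residual_strata,
    simulate_dataset,
)
from rfqt.stratify import largest_remainder_quotas

HALF = (0.5, 0.5)


class TestQuotas:
    @pytest.mark.parametrize(
        "props,size,expected",
        [
            ((0.3, 0.7), 10, [3, 7]),
            ((0.5, 0.5), 10, [5, 5]),
            ((0.7, 0.3), 10, [7, 3]),
            ((0.5, 0.5), 7, [4, 3]),
            ((0.1,) * 10, 10, [1] * 10),
            ((0.1,) * 10, 3, [1, 1, 1] + [0] * 7),
        ],
    )
    def test_hand_values(self, props, size, expected):
        assert largest_remainder_quotas(np.array(props), size).tolist() == expected

    @settings(max_examples=50, deadline=None)
    @given(
        k=st.integers(min_value=1, max_value=8),
        size=st.integers(min_value=0, max_value=100),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_quotas_sum_and_bounds(self, k, size, seed):
        rng = np.random.default_rng(seed)
        props = rng.dirichlet(np.ones(k))
        quotas = largest_remainder_quotas(props, size)
        assert quotas.sum() == size
        assert np.all(np.abs(quotas - props * size) < 1)


class TestNaive:
    def test_sorted_cut(self):
        assign = naive_strata(np.arange(1, 11, dtype=float), HALF, seed=0)
        assert assign.labels.tolist() == [1] * 5 + [2] * 5

    def test_tie_rule_exact_sizes(self):
        a1 = naive_strata(np.ones(10), HALF, seed=3)
        a2 = naive_strata(np.ones(10), HALF, seed=3)
        assert a1.sizes().tolist() == [5, 5]
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_unequal_proportions(self):
        assign = naive_strata(np.arange(10, dtype=float), (0.3, 0.7), seed=0)
        assert assign.sizes().tolist() == [3, 7]

    def test_too_many_strata(self):
        with pytest.raises(ValueError):
            naive_strata(np.arange(2, dtype=float), (0.25, 0.25, 0.25, 0.25), seed=0)


class TestResidual:
    def test_hand_ols(self):
        # Z=(0,0,1,1), M=(1,3,4,6): OLS M = 2 + 3Z, residuals (-1,1,-1,1)
        assign = residual_strata([1, 3, 4, 6], [0, 0, 1, 1], HALF, seed=0)
        assert assign.labels.tolist() == [1, 2, 1, 2]

    def test_perfect_fit_falls_back_to_ties(self):
        z = np.arange(10, dtype=float)
        assign = residual_strata(2 * z, z, HALF, seed=1)
        assert assign.sizes().tolist() == [5, 5]

    def test_constant_instrument_errors(self):
        with pytest.raises(ValueError, match="constant"):
            residual_strata(np.arange(4, dtype=float), np.ones(4), HALF, seed=0)

    def test_agrees_with_naive_when_instrument_irrelevant(self):
        rng = np.random.default_rng(5)
        n = 10_000
        z = rng.standard_normal(n)
        m = rng.standard_normal(n)  # independent of z: slope ~ 0
        res = residual_strata(m, z, HALF, seed=9)
        nai = naive_strata(m, HALF, seed=9)
        assert np.mean(res.labels == nai.labels) > 0.95


class TestDoublyRanked:
    def test_monotone_covariate(self):
        z = np.arange(1, 21, dtype=float)
        assign = doubly_ranked_strata(z, z, HALF, seed=0)
        # pre-strata are instrument ranks 1-10 and 11-20; the lower 5
        # covariate values of each go to stratum 1
        expected = [1] * 5 + [2] * 5 + [1] * 5 + [2] * 5
        assert assign.labels.tolist() == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_each_prestratum_contributes_equally(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        z = rng.standard_normal(n)
        m = rng.standard_normal(n)
        assign = doubly_ranked_strata(z, m, HALF, seed=seed)
        order = np.argsort(z)
        for g in range(n // 10):
            block = assign.labels[order[g * 10:(g + 1) * 10]]
            assert np.bincount(block, minlength=3)[1:].tolist() == [5, 5]

    def test_remainder_prestratum_kept(self):
        rng = np.random.default_rng(0)
        n = 27  # last pre-stratum has 7 members, cut 4:3
        assign = doubly_ranked_strata(rng.standard_normal(n), rng.standard_normal(n), HALF, seed=0)
        assert assign.labels.size == n
        assert assign.sizes().sum() == n
        assert assign.sizes().tolist() == [14, 13]

    def test_instrument_balanced_across_strata(self):
        # scenario B collider covariate: doubly-ranked strata stay balanced
        # in the instrument while naive strata do not
        sim = simulate_dataset(SimConfig(n=5000, scenario="B", pure_null=True, seed=21))
        z = sim.data.Z
        m2 = sim.data.covariate("M2")
        dr = doubly_ranked_strata(z, m2, HALF, seed=1)
        nai = naive_strata(m2, HALF, seed=1)
        se = np.sqrt(2 / 2500)  # SE of a mean difference of standard normals
        dr_diff = abs(z[dr.labels == 1].mean() - z[dr.labels == 2].mean())
        naive_diff = abs(z[nai.labels == 1].mean() - z[nai.labels == 2].mean())
        assert dr_diff < 3 * se
        assert naive_diff > 4 * se

    def test_row_order_invariance_without_ties(self):
        rng = np.random.default_rng(8)
        n = 40
        z = rng.standard_normal(n)
        m = rng.standard_normal(n)
        base = doubly_ranked_strata(z, m, HALF, seed=3)
        perm = rng.permutation(n)
        permuted = doubly_ranked_strata(z[perm], m[perm], HALF, seed=3)
        # tie-free data: the (value, label) pairing is order-invariant
        assert sorted(zip(z, base.labels)) == sorted(zip(z[perm], permuted.labels))

    def test_discrete_covariate_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="discrete"):
            doubly_ranked_strata(rng.standard_normal(100),
                                 rng.integers(0, 2, 100).astype(float), HALF, seed=0)


class TestDeciles:
    def test_one_per_prestratum(self):
        rng = np.random.default_rng(2)
        assign = doubly_ranked_deciles(rng.standard_normal(100), rng.standard_normal(100), K=10, seed=0)
        assert assign.sizes().tolist() == [10] * 10

    def test_consistent_with_general_call(self):
        rng = np.random.default_rng(4)
        z, m = rng.standard_normal(60), rng.standard_normal(60)
        a = doubly_ranked_deciles(z, m, K=2, seed=5)
        b = doubly_ranked_strata(z, m, np.array([0.5, 0.5]), seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_stratum_covariate_means_increase(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(500)
        m = z + 0.1 * rng.standard_normal(500)  # monotone-ish in instrument rank
        assign = doubly_ranked_deciles(z, m, K=10, seed=0)
        means = [m[assign.labels == k].mean() for k in range(1, 11)]
        assert np.all(np.diff(means) > 0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            doubly_ranked_deciles(np.arange(20.0), np.arange(20.0), K=1)
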
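import numpy as np
import pytest

from rfqt import (
    Forest,
    QTreeHyperparameters,
    SimConfig,
    fit_rfqt,
    grow_qtree,
    oob_predict,
    permutation_test,
    predict_qtree,
    predict_rfqt,
    s1_statistic,
    s2_statistic,
    simulate_dataset,
    variable_importance,
)
from rfqt.tree import QTree, TreeNode

SMALL = QTreeHyperparameters(min_node_size=200)


def leaf(index, depth, n, theta, beta_X=1.0, sigma_X=0.0, sigma_Y=1.0):
    return TreeNode(
        index=index, depth=depth, n=n, theta=theta, theta_se=sigma_Y,
        beta_X=beta_X, sigma_X=sigma_X, beta_Y=theta * beta_X, sigma_Y=sigma_Y,
    )


def stump(thetas, sizes, **leaf_kwargs):
    """Hand-built one-split tree with the given leaf estimates and sizes."""
    root = leaf(0, 0, sum(sizes), np.average(thetas, weights=sizes))
    root.covariate = "M1"
    root.proportion = (0.5, 0.5)
    root.boundary = 0.0
    root.q_value = 5.0
    root.child_means = (-1.0, 1.0)
    root.children = (1, 2)
    nodes = [root] + [
        leaf(i + 1, 1, sz, th, **leaf_kwargs)
        for i, (th, sz) in enumerate(zip(thetas, sizes))
    ]
    return QTree(nodes=nodes, hyper=QTreeHyperparameters(),
                 covariate_names=("M1",), n_fit=sum(sizes))


def single_leaf_tree(theta=0.7, n=100):
    return QTree(nodes=[leaf(0, 0, n, theta)], hyper=QTreeHyperparameters(),
                 covariate_names=("M1",), n_fit=n)


def manual_forest(trees):
    return Forest(trees=trees, bootstrap_ids=None,
                  hyper=trees[0].hyper, n_train=trees[0].n_fit)


class TestFit:
    def test_single_tree_degenerate_config(self, modified_sim):
        data = modified_sim.data
        forest = fit_rfqt(data, SMALL, N_B=1, seed=9, bootstrap=False)
        seed0 = np.random.SeedSequence(9).spawn(1)[0]
        tree = grow_qtree(data, SMALL, seed=np.random.default_rng(seed0))
        np.testing.assert_array_equal(
            predict_rfqt(forest, data.M), predict_qtree(tree, data.M)
        )

    def test_mtry_eleven_of_twentyeight(self):
        sim = simulate_dataset(SimConfig(n=600, scenario="A", gamma=0.5, p=28, seed=1))
        from rfqt.tree import grow_qtree as grow

        # 40% of 28 covariates -> 11 candidates at each node
        assert round(0.4 * sim.data.p) == 11
        forest = fit_rfqt(sim.data, SMALL.replace(mtry_fraction=0.4), N_B=2, seed=0)
        assert forest.hyper.mtry_fraction == 0.4

    def test_same_seed_identical(self, modified_sim):
        data = modified_sim.data
        f1 = fit_rfqt(data, SMALL, N_B=5, seed=3)
        f2 = fit_rfqt(data, SMALL, N_B=5, seed=3)
        np.testing.assert_array_equal(predict_rfqt(f1, data.M), predict_rfqt(f2, data.M))

    def test_bootstrap_sample_sizes(self, null_sim):
        forest = fit_rfqt(null_sim.data, SMALL, N_B=3, seed=0)
        for boot in forest.bootstrap_ids:
            assert boot.size == null_sim.data.n

    def test_json_round_trip(self, modified_sim):
        data = modified_sim.data
        forest = fit_rfqt(data, SMALL, N_B=3, seed=4)
        restored = Forest.from_json(forest.to_json())
        np.testing.assert_array_equal(
            predict_rfqt(forest, data.M), predict_rfqt(restored, data.M)
        )


class TestPredict:
    def test_constant_forest(self):
        forest = manual_forest([single_leaf_tree(0.7), single_leaf_tree(0.7)])
        np.testing.assert_allclose(predict_rfqt(forest, np.zeros((4, 1))), 0.7)

    def test_mean_of_two_trees(self):
        forest = manual_forest([single_leaf_tree(0.0), single_leaf_tree(1.0)])
        np.testing.assert_allclose(predict_rfqt(forest, np.zeros((4, 1))), 0.5)

    def test_exact_mean_of_tree_predictions(self, modified_sim):
        data = modified_sim.data
        forest = fit_rfqt(data, SMALL, N_B=4, seed=5)
        per_tree = np.stack([predict_qtree(t, data.M) for t in forest.trees])
        np.testing.assert_allclose(predict_rfqt(forest, data.M), per_tree.mean(axis=0))

    def test_held_out_correlation_with_truth(self):
        sim = simulate_dataset(SimConfig(n=10_000, scenario="A", gamma=0.5, seed=77))
        from rfqt import split_train_test

        train, test = split_train_test(sim.data, 2 / 3, seed=1)
        forest = fit_rfqt(train, QTreeHyperparameters(min_node_size=1000), N_B=50, seed=2)
        pred = predict_rfqt(forest, test.M)
        truth = sim.true_effect[test.ids]
        assert np.corrcoef(pred, truth)[0, 1] > 0.5


class TestOOB:
    def test_single_tree_oob_fraction(self, null_sim):
        forest = fit_rfqt(null_sim.data, SMALL, N_B=1, seed=6)
        _, counts = oob_predict(forest, null_sim.data)
        frac = np.mean(counts > 0)
        assert abs(frac - np.exp(-1)) < 0.04  # ~3 binomial SDs at n=4000

    def test_no_bootstrap_flagged(self, null_sim):
        forest = fit_rfqt(null_sim.data, SMALL, N_B=2, seed=0, bootstrap=False)
        est, counts = oob_predict(forest, null_sim.data)
        assert np.all(np.isnan(est))
        assert np.all(counts == 0)

    def test_oob_mse_stabilizes_with_forest_size(self):
        sim = simulate_dataset(SimConfig(n=4000, scenario="A", gamma=0.5, seed=55))
        forest = fit_rfqt(sim.data, SMALL.replace(min_node_size=500), N_B=60, seed=1)
        half = Forest(trees=forest.trees[:30], bootstrap_ids=forest.bootstrap_ids[:30],
                      hyper=forest.hyper, n_train=forest.n_train)
        mses = []
        for f in (half, forest):
            est, counts = oob_predict(f, sim.data)
            ok = counts > 0
            mses.append(np.mean((est[ok] - sim.true_effect[ok]) ** 2))
        assert abs(mses[1] - mses[0]) < 0.05 * mses[0]


class TestVariableImportance:
    def test_unused_covariate_scores_zero(self, modified_sim):
        forest = fit_rfqt(modified_sim.data, SMALL, N_B=5, seed=7)
        vi = variable_importance(forest, modified_sim.data, seed=0)
        used = set().union(*(
            {n.covariate for n in t.nodes if n.covariate is not None}
            for t in forest.trees
        ))
        unused = [c for c in modified_sim.data.covariate_names if c not in used]
        for c in unused:
            assert vi.loc[c, "importance"] == 0.0

    def test_nonnegative_and_ranks_are_permutation(self, modified_sim):
        forest = fit_rfqt(modified_sim.data, SMALL, N_B=5, seed=8)
        vi = variable_importance(forest, modified_sim.data, seed=1)
        assert (vi["importance"] >= 0).all()
        assert sorted(vi["rank"]) == list(range(1, modified_sim.data.p + 1))

    def test_modifiers_outrank_noise(self, modified_sim):
        forest = fit_rfqt(modified_sim.data, SMALL, N_B=20, seed=9)
        vi = variable_importance(forest, modified_sim.data, seed=2)
        modifier_mean = vi.loc[["M1", "M2", "M3", "M4", "M5"], "importance"].mean()
        noise_mean = vi.loc[[f"M{j}" for j in range(6, 21)], "importance"].mean()
        assert modifier_mean > noise_mean


class TestHeterogeneityStatistics:
    def test_s1_zero_for_single_leaf_trees(self):
        forest = manual_forest([single_leaf_tree(), single_leaf_tree()])
        assert s1_statistic(forest) == 0.0
        assert s2_statistic(forest) == 0.0

    def test_s1_hand_value(self):
        # one tree, two equal leaves with estimates 0 and 1:
        # weighted mean 0.5, S1 = 0.5*(0.25) + 0.5*(0.25) = 0.25
        forest = manual_forest([stump([0.0, 1.0], [50, 50])])
        assert s1_statistic(forest) == pytest.approx(0.25)

    def test_s1_invariant_to_duplicating_trees(self):
        t = stump([0.0, 1.0], [30, 70])
        assert s1_statistic(manual_forest([t])) == pytest.approx(
            s1_statistic(manual_forest([t, t]))
        )

    def test_s2_zero_under_exact_proportionality(self):
        forest = manual_forest([stump([0.8, 0.8], [50, 50])])
        assert s2_statistic(forest) == pytest.approx(0.0)

    def test_s2_reproduces_hand_q(self):
        # leaves mirror the two-stratum worked example with Q = 0.5
        forest = manual_forest([stump([0.0, 1.0], [50, 50])])
        assert s2_statistic(forest) == pytest.approx(0.5)

    def test_s2_equals_mean_of_per_tree_q(self, modified_sim):
        from scipy import stats as sps

        forest = fit_rfqt(modified_sim.data, SMALL, N_B=4, seed=10)
        total = 0.0
        for tree in forest.trees:
            leaves = tree.leaves()
            if len(leaves) < 2:
                continue
            bX = np.array([lf.beta_X for lf in leaves])
            sX = np.array([lf.sigma_X for lf in leaves])
            bY = np.array([lf.beta_Y for lf in leaves])
            sY = np.array([lf.sigma_Y for lf in leaves])
            w = bX**2 / sY**2
            theta = np.sum(w * bY / bX) / np.sum(w)
            total += np.sum((bY - theta * bX) ** 2 / (sY**2 + theta**2 * sX**2))
        assert s2_statistic(forest) == pytest.approx(total / forest.N_B)


class TestPermutationTest:
    def test_counting_rules_and_determinism(self, null_sim):
        data = null_sim.data.subset(np.arange(1000))
        hyper = SMALL.replace(min_node_size=100, max_depth=2)
        res = permutation_test(data, hyper, N_B=3, n_perm=12, seed=1)
        r1 = int(np.sum(res.s1_null >= res.s1_observed))
        r2 = int(np.sum(res.s2_null >= res.s2_observed))
        assert res.p1 == pytest.approx(r1 / 12)
        assert res.p2 == pytest.approx(r2 / 12)
        plus = permutation_test(data, hyper, N_B=3, n_perm=12, seed=1, plus_one=True)
        assert plus.p1 == pytest.approx((r1 + 1) / 13)
        np.testing.assert_array_equal(res.s2_null, plus.s2_null)

    def test_modified_data_rejects(self):
        sim = simulate_dataset(SimConfig(n=6000, scenario="A", gamma=0.5, seed=45))
        res = permutation_test(sim.data, QTreeHyperparameters(min_node_size=1000),
                               N_B=20, n_perm=9, seed=3)
        assert res.p2 == 0.0  # observed S2 above every permutation null
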
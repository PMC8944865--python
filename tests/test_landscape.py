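import numpy as np
import pandas as pd
import pytest

import sleepscape as ss
from sleepscape.landscape import (
    ClusterNode,
    ClusterTree,
    auto_eps,
    cluster_profiles,
    density_cluster,
    divisive_cluster,
    embed,
    evaluate_recovery,
    outlier_cluster,
    select_outliers,
    ward_regroup,
    zscore,
)

from oracles import naive_ari, naive_ward_merge_order


def blob_table(sizes, sep=10.0, sd=1.0, dims=21, seed=0):
    """Gaussian clusters whose centers differ across all index columns.

    Mirrors how real phenotype archetypes differ in many indexes at once;
    a separation confined to one or two columns would be flattened by the
    column-wise standardization.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, n in enumerate(sizes):
        center = rng.normal(0, sep, size=dims)
        rows.append(rng.normal(0, sd, size=(n, dims)) + center)
        labels += [i] * n
    X = np.vstack(rows)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))]), np.array(labels)


class TestZscore:
    def test_two_point_convention(self):
        """Sample-SD (n-1) standardization: {0, 2} -> {-0.707, +0.707}."""
        table = pd.DataFrame({"a": [0.0, 2.0]})
        z = zscore(table)
        assert z.values["a"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_columns_standardized(self, rng):
        table = pd.DataFrame(rng.normal(5, 3, size=(100, 4)))
        z = zscore(table)
        assert np.allclose(z.values.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.values.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_warns_and_zeroes(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore(table)
        assert np.all(z.values["b"] == 0.0)

    def test_inverse_round_trip(self, rng):
        table = pd.DataFrame(rng.normal(2, 7, size=(50, 3)))
        z = zscore(table)
        assert np.allclose(z.inverse().to_numpy(), table.to_numpy(), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            zscore(pd.DataFrame({"a": [1.0, np.nan, 2.0]}))


class TestEmbed:
    def test_pca_preserves_distances_in_3d(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)))
        emb = embed(X, method="pca", seed=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X.to_numpy()), pdist(emb), atol=1e-6)

    def test_blob_separation(self):
        table, labels = blob_table([50, 50], seed=1)
        emb = embed(zscore(table), seed=0, n_neighbors=15)
        d01 = np.linalg.norm(emb[labels == 0].mean(0) - emb[labels == 1].mean(0))
        within = np.linalg.norm(emb[labels == 0] - emb[labels == 0].mean(0), axis=1)
        assert d01 > np.percentile(within, 95)

    def test_seed_determinism(self):
        table, _ = blob_table([60], seed=2)
        e1 = embed(zscore(table), seed=3)
        e2 = embed(zscore(table), seed=3)
        assert np.array_equal(e1, e2)

    def test_unknown_method(self):
        table, _ = blob_table([10], seed=0)
        with pytest.raises(ValueError):
            embed(table, method="isomap")


class TestDensityCluster:
    def test_two_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (40, 3)), rng.normal(5, 0.1, (40, 3))])
        labels = density_cluster(X, eps=0.5, min_samples=5)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_isolated_point_is_noise(self):
        X = np.array([[0.0, 0, 0], [0.01, 0, 0], [5.0, 5, 5]])
        labels = density_cluster(X, eps=0.1, min_samples=2)
        assert labels[2] == -1

    def test_identical_points_single_cluster(self):
        X = np.zeros((30, 3))
        labels = density_cluster(X, eps=0.1, min_samples=5)
        assert set(labels) == {0}

    def test_auto_eps_positive(self, rng):
        X = rng.normal(size=(50, 3))
        assert auto_eps(X, 10) > 0


class TestDivisiveCluster:
    def test_planted_blobs_recovered(self):
        table, truth = blob_table([80, 80, 80, 80], seed=4)
        tree = divisive_cluster(table, seed=0, n_neighbors=15)
        labels = tree.labels()
        assert len(tree.leaves()) >= 4
        assert evaluate_recovery(labels, truth) >= 0.8

    def test_homogeneous_cloud_single_leaf(self):
        table, _ = blob_table([300], sep=0.0, seed=5)
        tree = divisive_cluster(table, seed=0)
        assert len(tree.leaves()) == 1

    def test_small_table_rejected(self):
        table, _ = blob_table([19], seed=0)
        with pytest.raises(ValueError):
            divisive_cluster(table, min_child_size=20)

    def test_children_partition_parent(self):
        table, _ = blob_table([100, 100], seed=6)
        tree = divisive_cluster(table, seed=0, n_neighbors=15)

        def check(node):
            if node.children:
                union = np.concatenate([c.members for c in node.children])
                both = np.concatenate([union, node.noise])
                assert sorted(both.tolist()) == sorted(node.members.tolist())
                assert len(set(union) & set(node.noise)) == 0
                for c in node.children:
                    check(c)

        check(tree.root)

    def test_max_depth_respected(self):
        table, _ = blob_table([100, 100], seed=7)
        tree = divisive_cluster(table, max_depth=1, seed=0, n_neighbors=15)
        assert all(leaf.depth <= 1 for leaf in tree.leaves())


def manual_tree(profile_points, per_leaf=5, n_first_layers=1):
    """Build a ClusterTree by hand: leaves with identical rows per profile."""
    rows = []
    leaves = []
    idx = 0
    for p in profile_points:
        members = np.arange(idx, idx + per_leaf)
        rows += [p] * per_leaf
        leaves.append(ClusterNode(members=members, depth=2, node_id=f"leaf{idx}"))
        idx += per_leaf
    X = pd.DataFrame(np.array(rows, dtype=float), index=[f"s{i}" for i in range(idx)])
    if n_first_layers == 1:
        top = ClusterNode(members=np.arange(idx), depth=1, node_id="1", children=leaves)
        root = ClusterNode(members=np.arange(idx), depth=0, node_id="root", children=[top])
    else:
        half = len(leaves) // 2
        n1 = np.concatenate([l.members for l in leaves[:half]])
        n2 = np.concatenate([l.members for l in leaves[half:]])
        t1 = ClusterNode(members=n1, depth=1, node_id="1", children=leaves[:half])
        t2 = ClusterNode(members=n2, depth=1, node_id="2", children=leaves[half:])
        root = ClusterNode(members=np.arange(idx), depth=0, node_id="root", children=[t1, t2])
    tree = ClusterTree(root, X.index)
    return tree, X


class TestWardRegroup:
    def test_identical_profiles_merged(self):
        tree, X = manual_tree([[0.0, 0.0], [0.0, 0.0]])
        z = zscore(X + np.random.default_rng(0).normal(0, 1e-9, X.shape))
        labels = ward_regroup(tree, z, 1)
        assert set(labels) == {"1"}

    def test_cross_first_layer_never_merged(self):
        tree, X = manual_tree([[0, 0], [0, 0], [0, 0], [0, 0]], n_first_layers=2)
        z = zscore(X + np.random.default_rng(0).normal(0, 1e-9, X.shape))
        labels = ward_regroup(tree, z, 1)
        # identical profiles, but two first-layer clusters stay distinct
        assert set(labels) == {"1", "2"}

    def test_merge_order_matches_textbook_ward(self):
        """Scipy's Ward agglomeration of 4 profiles equals the hand formula."""
        points = [[0.0, 0.0], [0.0, 1.0], [5.0, 0.0], [5.2, 0.8]]
        order = naive_ward_merge_order(points)
        from scipy.cluster.hierarchy import linkage

        link = linkage(np.array(points), method="ward")
        sets = {}
        for i in range(4):
            sets[i] = frozenset([i])
        scipy_order = []
        for row_idx, (a, b, _, _) in enumerate(link):
            merged = sets[int(a)] | sets[int(b)]
            scipy_order.append(merged)
            sets[4 + row_idx] = merged
        assert scipy_order == order

    def test_grouping_respects_profile_geometry(self):
        # two tight pairs of profiles -> cut at 2 groups recovers the pairs
        tree, X = manual_tree([[0, 0], [0, 0.5], [10, 0], [10, 0.5]])
        z = zscore(X + np.random.default_rng(1).normal(0, 1e-6, X.shape))
        labels = ward_regroup(tree, z, 2)
        s = labels.to_numpy()
        assert len(set(s[:10])) == 1 and len(set(s[10:])) == 1
        assert s[0] != s[10]

    def test_too_many_groups_rejected(self):
        tree, X = manual_tree([[0, 0], [1, 1]])
        z = zscore(X + np.random.default_rng(0).normal(0, 1e-9, X.shape))
        with pytest.raises(ValueError):
            ward_regroup(tree, z, 5)


class TestSelectOutliers:
    def test_pct_50_flags_everyone(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=101)})
        assert select_outliers(table, ["a"], pct=50.0).all()

    def test_tail_counts_match_rank_brute_force(self, rng):
        n = 10_000
        vals = rng.permutation(np.arange(n, dtype=float))
        table = pd.DataFrame({"a": vals})
        mask = select_outliers(table, ["a"], pct=2.28)
        lo_q = np.percentile(vals, 2.28)
        hi_q = np.percentile(vals, 97.72)
        brute = np.sum(vals <= lo_q) + np.sum(vals >= hi_q)
        assert mask.sum() == brute
        assert 450 <= mask.sum() <= 460  # ~228 per tail

    def test_union_idempotent(self, rng):
        # a subject extreme in 2 of 3 indexes is flagged once
        table = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        table.iloc[0] = [100.0, 100.0, 0.0]
        mask = select_outliers(table, list("abc"))
        assert mask.iloc[0] and mask.dtype == bool

    def test_unknown_index_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            select_outliers(table, ["b"])

    def test_independent_uniform_fraction(self, rng):
        """Flagged fraction approaches 1 - (1 - 2p)^6 for independent indexes."""
        n = 20_000
        table = pd.DataFrame(rng.uniform(size=(n, 6)), columns=list("abcdef"))
        frac = select_outliers(table, list("abcdef"), pct=2.28).mean()
        p = 1 - (1 - 2 * 0.0228) ** 6
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se + 2 * 6 / n  # + boundary-inclusion slack


class TestOutlierCluster:
    def test_two_extreme_archetypes(self):
        table, truth = blob_table([40, 40], seed=8)
        labels = outlier_cluster(table, seed=0, min_samples=10, n_neighbors=15)
        assert len(set(labels) - {-1}) == 2

    def test_identical_rows_single_cluster(self):
        table = pd.DataFrame(np.ones((25, 4)))
        labels = outlier_cluster(table, seed=0)
        assert set(labels) == {0}

    def test_determinism(self):
        table, _ = blob_table([40], seed=9)
        l1 = outlier_cluster(table, seed=1, min_samples=10, n_neighbors=15)
        l2 = outlier_cluster(table, seed=1, min_samples=10, n_neighbors=15)
        assert l1.equals(l2)

    def test_too_small_subset(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            outlier_cluster(table, min_samples=20)


class TestClusterProfiles:
    def test_single_cluster_profile_near_zero(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 4)))
        z = zscore(table)
        labels = pd.Series(0, index=table.index)
        profs = cluster_profiles(labels, z)
        assert len(profs) == 1
        assert np.allclose(profs[0].mean_z, 0.0, atol=1e-9)

    def test_singleton_cluster_equals_row(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 3)))
        z = zscore(table)
        labels = pd.Series([0] * 9 + [1], index=table.index)
        profs = cluster_profiles(labels, z)
        one = [p for p in profs if p.label == 1][0]
        assert np.allclose(one.mean_z, z.values.iloc[-1])
        assert one.representative == table.index[-1]

    def test_sizes_sum_excluding_noise(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 3)))
        z = zscore(table)
        labels = pd.Series([0] * 10 + [1] * 15 + [-1] * 5, index=table.index)
        profs = cluster_profiles(labels, z)
        assert sum(p.size for p in profs) == 25


class TestEvaluateRecovery:
    def test_identical_partitions(self):
        assert evaluate_recovery([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_singletons_vs_single_cluster(self):
        assert evaluate_recovery([0, 1, 2, 3], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_matches_contingency_formula(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 1, 2, 0]
        assert evaluate_recovery(a, b) == pytest.approx(naive_ari(a, b))

    def test_noise_excluded_pairwise(self):
        got = evaluate_recovery([0, 0, -1, 1], [1, 1, 1, 2])
        assert got == 1.0

    def test_all_noise_rejected(self):
        with pytest.raises(ValueError):
            evaluate_recovery([-1, -1], [0, 1])
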
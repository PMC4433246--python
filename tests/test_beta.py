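import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import braycurtis

import _oracles
from gutcore.beta import (
    binary_jaccard,
    distance_boxplot_tests,
    distance_group_stats,
    jackknife_beta,
    manhattan_distance,
    unweighted_unifrac,
    weighted_unifrac,
)
from gutcore.simulate import generate_tree
from gutcore.table import OtuTable


def table_of(rows, otus, samples=None, marker="V12"):
    arr = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    return OtuTable(pd.DataFrame(arr, index=samples, columns=otus), marker)


class TestJaccard:
    def test_identical_disjoint_and_half(self):
        t = table_of(
            [[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 5], [0, 1, 1, 1]],
            otus=list("abcd"),
        )
        dm = binary_jaccard(t)
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0
        assert dm["s0", "s3"] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}

    @given(arrays(np.int64, (4, 6), elements=st.integers(0, 3)))
    def test_triangle_inequality(self, counts):
        counts[:, 0] += 1
        t = table_of(counts, otus=[f"o{i}" for i in range(6)])
        d = np.asarray(binary_jaccard(t).data)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestManhattan:
    def test_identical_rows_and_hand_pair(self):
        frame = pd.DataFrame(
            [[0.2, 0.3, 0.5], [0.2, 0.3, 0.5], [0.5, 0.1, 0.4]],
            index=["a", "b", "c"],
        )
        dm = manhattan_distance(frame)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == pytest.approx(0.3 + 0.2 + 0.1)

    def test_equals_twice_bray_curtis_on_fractions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.dirichlet(np.ones(8))
            y = rng.dirichlet(np.ones(8))
            frame = pd.DataFrame([x, y], index=["x", "y"])
            dm = manhattan_distance(frame)
            assert dm["x", "y"] == pytest.approx(2 * braycurtis(x, y), abs=1e-12)

    @given(arrays(np.float64, (4, 5), elements=st.floats(0, 1)))
    def test_triangle_inequality(self, values):
        frame = pd.DataFrame(values, index=list("wxyz"))
        d = np.asarray(manhattan_distance(frame).data)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestUniFrac:
    def test_identical_samples_are_zero(self, four_tip_tree):
        t = table_of([[3, 1, 0, 2], [3, 1, 0, 2]], otus=list("ABCD"))
        assert unweighted_unifrac(t, four_tip_tree)["s0", "s1"] == 0.0
        assert weighted_unifrac(t, four_tip_tree)["s0", "s1"] == 0.0

    def test_disjoint_samples_on_star_tree(self):
        star = skbio.TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        t = table_of([[2, 3, 0, 0], [0, 0, 1, 4]], otus=list("ABCD"))
        assert unweighted_unifrac(t, star)["s0", "s1"] == 1.0
        assert weighted_unifrac(t, star)["s0", "s1"] == 1.0

    def test_matches_naive_edge_enumeration(self):
        rng = np.random.default_rng(1)
        for rep in range(10):
            tree = generate_tree(8, seed_or_rng=rng)
            otus = [t.name for t in tree.tips()]
            counts = rng.integers(0, 6, size=(3, 8))
            counts[:, 0] += 1
            t = table_of(counts, otus=otus)
            uw = unweighted_unifrac(t, tree)
            w = weighted_unifrac(t, tree)
            for i in range(3):
                for j in range(i + 1, 3):
                    pa = [o for k, o in enumerate(otus) if counts[i, k] > 0]
                    pb = [o for k, o in enumerate(otus) if counts[j, k] > 0]
                    assert uw[f"s{i}", f"s{j}"] == pytest.approx(
                        _oracles.naive_unweighted_unifrac(tree, pa, pb), abs=1e-10
                    )
                    ca = dict(zip(otus, counts[i]))
                    cb = dict(zip(otus, counts[j]))
                    assert w[f"s{i}", f"s{j}"] == pytest.approx(
                        _oracles.naive_weighted_unifrac(tree, ca, cb), abs=1e-10
                    )

    def test_matches_reference_implementation(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(2)
        tree = generate_tree(10, seed_or_rng=rng)
        otus = [t.name for t in tree.tips()]
        counts = rng.integers(0, 5, size=(4, 10))
        counts[:, 0] += 1
        t = table_of(counts, otus=otus)
        ref_u = beta_diversity(
            "unweighted_unifrac", counts, ids=t.sample_ids, taxa=otus, tree=tree
        )
        ref_w = beta_diversity(
            "weighted_unifrac", counts, ids=t.sample_ids, taxa=otus, tree=tree,
            normalized=True,
        )
        assert np.allclose(np.asarray(unweighted_unifrac(t, tree).data),
                           np.asarray(ref_u.data), atol=1e-10)
        assert np.allclose(np.asarray(weighted_unifrac(t, tree).data),
                           np.asarray(ref_w.data), atol=1e-10)

    def test_unweighted_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        tree = generate_tree(6, seed_or_rng=rng)
        counts = rng.integers(0, 4, (5, 6))
        counts[:, 0] += 1
        t = table_of(counts, otus=[x.name for x in tree.tips()])
        d = np.asarray(unweighted_unifrac(t, tree).data)
        assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()

    def test_table_otu_missing_from_tree_is_error(self, four_tip_tree):
        t = table_of([[1, 1]], otus=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            unweighted_unifrac(t, four_tip_tree)


class TestDistanceSummaries:
    @pytest.fixture
    def dm_and_groups(self):
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.7],
                [0.1, 0.0, 0.5, 0.8],
                [0.6, 0.5, 0.0, 0.2],
                [0.7, 0.8, 0.2, 0.0],
            ]
        )
        dm = skbio.DistanceMatrix(d, ids=["a1", "a2", "b1", "b2"])
        groups = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        return dm, groups

    def test_hand_computed_group_stats(self, dm_and_groups):
        dm, groups = dm_and_groups
        stats = distance_group_stats(dm, groups)
        assert stats.at["within A", "mean"] == pytest.approx(0.1)
        assert stats.at["within B", "mean"] == pytest.approx(0.2)
        assert stats.at["A vs B", "mean"] == pytest.approx((0.6 + 0.7 + 0.5 + 0.8) / 4)
        assert stats.at["A vs B", "n_pairs"] == 4

    def test_single_member_group_flagged_as_nan(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        dm = skbio.DistanceMatrix(d, ids=["x", "y", "z"])
        groups = pd.Series(["G", "G", "lone"], index=["x", "y", "z"])
        stats = distance_group_stats(dm, groups)
        assert stats.at["within lone", "n_pairs"] == 0
        assert np.isnan(stats.at["within lone", "mean"])

    def test_boxplot_tests_bonferroni_definition(self, dm_and_groups):
        dm, groups = dm_and_groups
        out = distance_boxplot_tests(dm, groups)
        k = len(out)
        assert (out["p_bonferroni"] == (out["p"] * k).clip(upper=1.0)).all()

    def test_identical_distributions_not_significant(self):
        # two categories drawn from an identical set of values
        d = np.zeros((6, 6))
        vals = [0.5, 0.6, 0.7]
        idx = np.triu_indices(6, 1)
        rng = np.random.default_rng(0)
        d[idx] = rng.permutation(np.tile(vals, 5))
        d = d + d.T
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        groups = pd.Series(
            ["A", "A", "A", "B", "B", "B"], index=[f"s{i}" for i in range(6)]
        )
        out = distance_boxplot_tests(dm, groups)
        assert (out["p_bonferroni"] > 0.05).all()


class TestJackknife:
    def make_clustered_table(self, rng):
        # two clear clusters of 4 samples sharing distinct OTU blocks
        block = np.zeros((8, 20), dtype=int)
        block[:4, :10] = rng.integers(20, 40, (4, 10))
        block[4:, 10:] = rng.integers(20, 40, (4, 10))
        block[:, 0] += 1  # keep rows non-empty everywhere
        return OtuTable(
            pd.DataFrame(
                block,
                index=[f"s{i}" for i in range(8)],
                columns=[f"o{j}" for j in range(20)],
            )
        )

    def test_single_replicate_support_is_binary(self):
        rng = np.random.default_rng(4)
        t = self.make_clustered_table(rng)
        res = jackknife_beta(t, depth=50, replicates=1, seed_or_rng=0)
        assert set(res.support.values()) <= {0.0, 1.0}

    def test_separated_clusters_get_full_support(self):
        rng = np.random.default_rng(5)
        t = self.make_clustered_table(rng)
        res = jackknife_beta(t, depth=50, replicates=30, seed_or_rng=0)
        cluster_a = frozenset(f"s{i}" for i in range(4))
        cluster_b = frozenset(f"s{i}" for i in range(4, 8))
        assert res.support.get(cluster_a, res.support.get(cluster_b)) >= 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        t = self.make_clustered_table(rng)
        r1 = jackknife_beta(t, depth=40, replicates=10, seed_or_rng=3)
        r2 = jackknife_beta(t, depth=40, replicates=10, seed_or_rng=3)
        assert r1.support == r2.support
        assert r1.tree_newick == r2.tree_newick
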
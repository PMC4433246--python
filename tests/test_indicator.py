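import numpy as np
import pandas as pd
import pytest

import _oracles
from gutcore.indicator import concordant_indicators, indval, indval_significance
from gutcore.table import OtuTable


def two_cluster_table(rng=None, n_per=5, n_taxa=6):
    rng = rng or np.random.default_rng(0)
    counts = rng.integers(0, 12, size=(2 * n_per, n_taxa))
    counts[:, 0] += 1
    samples = [f"A{i}" for i in range(n_per)] + [f"B{i}" for i in range(n_per)]
    t = OtuTable(
        pd.DataFrame(counts, index=samples, columns=[f"t{j}" for j in range(n_taxa)])
    )
    clusters = pd.Series(["A"] * n_per + ["B"] * n_per, index=samples)
    return t, clusters


class TestIndval:
    def test_exclusive_ubiquitous_taxon_scores_exactly_one(self):
        t, clusters = two_cluster_table()
        counts = t.data.copy()
        counts["marker_taxon"] = [3, 7, 2, 9, 4, 0, 0, 0, 0, 0]
        res = indval(OtuTable(counts), clusters)
        assert res.max_indval("marker_taxon") == 1.0
        assert res.assigned_cluster("marker_taxon") == "A"

    def test_uniform_taxon_scores_one_over_k(self):
        samples = [f"s{i}" for i in range(9)]
        frame = pd.DataFrame(
            {"u": [4] * 9, "v": [1] * 9}, index=samples
        )
        clusters = pd.Series(["a", "b", "c"] * 3, index=samples)
        res = indval(OtuTable(frame), clusters)
        assert np.allclose(res.values.loc["u"], 1 / 3)
        assert res.summary.at["u", "tie"]

    def test_absent_taxon_scores_zero_without_cluster(self):
        t, clusters = two_cluster_table()
        counts = t.data.copy()
        counts["ghost"] = 0
        res = indval(OtuTable(counts), clusters)
        assert res.max_indval("ghost") == 0.0
        assert res.assigned_cluster("ghost") is None

    @pytest.mark.parametrize("mode", ["relative", "raw"])
    def test_matches_brute_force_definition(self, mode):
        rng = np.random.default_rng(3)
        for rep in range(20):
            n_clusters = 2 + rep % 2
            counts = rng.integers(0, 10, size=(10, 8))
            counts[:, 0] += 1
            samples = [f"s{i}" for i in range(10)]
            t = OtuTable(
                pd.DataFrame(counts, index=samples, columns=[f"t{j}" for j in range(8)])
            )
            labels = [f"c{i % n_clusters}" for i in range(10)]
            clusters = pd.Series(labels, index=samples)
            res = indval(t, clusters, mode=mode)
            oracle = _oracles.brute_indval(
                t.data, clusters, use_relative=(mode == "relative")
            )
            for taxon in t.otu_ids:
                for c in sorted(set(labels)):
                    assert res.values.at[taxon, c] == pytest.approx(
                        oracle[taxon][c], abs=1e-12
                    )

    def test_specificity_rows_sum_to_one_and_values_bounded(self):
        t, clusters = two_cluster_table(np.random.default_rng(4))
        res = indval(t, clusters)
        present = t.data.sum(axis=0) > 0
        sums = res.specificity.sum(axis=1)
        assert np.allclose(sums[present], 1.0)
        assert ((res.values >= 0) & (res.values <= 1)).all().all()

    def test_single_cluster_rejected(self):
        t, clusters = two_cluster_table()
        with pytest.raises(ValueError):
            indval(t, pd.Series("only", index=t.sample_ids))


class TestIndvalSignificance:
    def test_exclusive_taxon_gets_smallest_achievable_p(self):
        t, clusters = two_cluster_table()
        counts = t.data.copy()
        counts["marker_taxon"] = [3, 7, 2, 9, 4, 0, 0, 0, 0, 0]
        p = indval_significance(OtuTable(counts), clusters, permutations=199, seed_or_rng=0)
        assert p["marker_taxon"] < 0.05

    def test_deterministic_under_seed(self):
        t, clusters = two_cluster_table(np.random.default_rng(5))
        p1 = indval_significance(t, clusters, permutations=99, seed_or_rng=7)
        p2 = indval_significance(t, clusters, permutations=99, seed_or_rng=7)
        assert (p1 == p2).all()

    def test_null_rejection_rate_near_nominal(self):
        """With labels carrying no signal, ~5% of taxa reject at 0.05."""
        rng = np.random.default_rng(6)
        rejections = total = 0
        for _ in range(15):
            counts = rng.integers(1, 10, size=(12, 20))
            samples = [f"s{i}" for i in range(12)]
            t = OtuTable(
                pd.DataFrame(counts, index=samples, columns=[f"t{j}" for j in range(20)])
            )
            clusters = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6), index=samples)
            p = indval_significance(t, clusters, permutations=99, seed_or_rng=rng)
            rejections += int((p < 0.05).sum())
            total += len(p)
        assert 0.0 <= rejections / total < 0.12


class TestConcordance:
    def make_result(self, assignments):
        """assignments: taxon -> (cluster, indval)."""
        taxa = list(assignments)
        clusters = sorted({c for c, _ in assignments.values()})
        values = pd.DataFrame(0.0, index=taxa, columns=clusters)
        rows = []
        for taxon, (c, v) in assignments.items():
            values.at[taxon, c] = v
            rows.append({"taxon": taxon, "cluster": c, "indval": v, "tie": False})
        summary = pd.DataFrame(rows).set_index("taxon")
        from gutcore.indicator import IndValResult

        return IndValResult(
            values=values,
            specificity=values.copy(),
            fidelity=values.copy(),
            summary=summary,
            mode="relative",
        )

    def test_two_marker_filter_logic(self):
        a = self.make_result(
            {
                "keep": ("X", 0.9),
                "one_sided": ("X", 0.9),
                "cluster_clash": ("X", 0.8),
                "weak": ("Y", 0.3),
            }
        )
        b = self.make_result(
            {
                "keep": ("X", 0.5),      # below 0.6 in one marker is fine
                "one_sided": ("X", 0.9),
                "cluster_clash": ("Y", 0.8),
                "weak": ("Y", 0.4),
            }
        )
        p_a = pd.Series(
            {"keep": 0.001, "one_sided": 0.001, "cluster_clash": 0.001, "weak": 0.001}
        )
        p_b = pd.Series(
            {"keep": 0.01, "one_sided": 0.9, "cluster_clash": 0.001, "weak": 0.001}
        )
        out = concordant_indicators(a, p_a, b, p_b)
        assert out["taxon"].tolist() == ["keep"]
        assert out.at[0, "cluster"] == "X"
        assert out.at[0, "indval_a"] == 0.9
        assert out.at[0, "indval_b"] == 0.5

    def test_empty_when_nothing_concordant(self):
        a = self.make_result({"t": ("X", 0.9)})
        b = self.make_result({"t": ("Y", 0.9)})
        p = pd.Series({"t": 0.001})
        assert len(concordant_indicators(a, p, b, p)) == 0
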
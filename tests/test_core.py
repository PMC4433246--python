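import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _oracles
from gutcore.core import (
    core_length_permutation_test,
    core_members,
    cross_marker_core,
    prevalence_count,
    relative_core_length,
    shared_otu_proportions,
)
from gutcore.metadata import SampleMetadata
from gutcore.table import OtuTable


def meta_for(species_counts, origin="wild"):
    rows = {}
    for sp, n in species_counts.items():
        for k in range(n):
            rows[f"{sp}_{k}"] = {
                "host_species": sp,
                "host_genus": f"g_{sp}",
                "host_tribe": "T",
                "diet": "omnivore",
                "origin": origin if not sp.endswith("LAB") else "lab",
            }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


def table_for(meta, presence, otus=None, marker="V12"):
    presence = np.atleast_2d(presence).astype(int)
    otus = otus or [f"o{j}" for j in range(presence.shape[1])]
    return OtuTable(
        pd.DataFrame(presence, index=meta.sample_ids, columns=otus), marker
    )


class TestCoreMembers:
    def test_ubiquitous_otu_is_core_at_any_threshold(self):
        meta = meta_for({"a": 3, "b": 2})
        t = table_for(meta, np.ones((5, 2)))
        assert "o0" in core_members(t, meta, prevalence=1.0)

    def test_exact_eighty_percent_boundary_of_25(self):
        """With 25 wild fish the ceiling threshold is 20: an OTU in 20
        individuals is core, one in 19 is not."""
        meta = meta_for({"a": 5, "b": 5, "c": 5, "d": 5, "e": 5})
        pres = np.ones((25, 2))
        # one absence per species -> 20/25 with every species represented
        pres[::5, 0] = 0
        pres[::5, 1] = 0
        pres[1, 1] = 0  # 19/25
        t = table_for(meta, pres)
        cs = core_members(t, meta, prevalence=0.8)
        assert prevalence_count(25, 0.8) == 20
        assert "o0" in cs and "o1" not in cs

    def test_missing_one_entire_species_excludes(self):
        meta = meta_for({"a": 3, "b": 2})
        pres = np.ones((5, 1))
        pres[3:, 0] = 0  # absent from species b entirely
        t = table_for(meta, pres)
        assert len(core_members(t, meta, prevalence=0.5)) == 0
        assert "o0" in core_members(
            t, meta, prevalence=0.5, require_every_species=False
        )

    def test_lab_samples_outside_wild_scope(self):
        meta = meta_for({"a": 3, "aLAB": 2})
        pres = np.zeros((5, 1))
        pres[:3, 0] = 1  # only the wild fish carry it
        t = table_for(meta, pres)
        assert "o0" in core_members(t, meta, prevalence=1.0, scope="wild")
        assert "o0" not in core_members(t, meta, prevalence=1.0, scope="all")

    @given(arrays(np.int64, (6, 8), elements=st.integers(0, 3)))
    def test_monotone_in_threshold_and_criteria(self, counts):
        meta = meta_for({"a": 3, "b": 3})
        t = table_for(meta, counts)
        lo = set(core_members(t, meta, prevalence=0.5, require_every_species=False).members)
        hi = set(core_members(t, meta, prevalence=0.9, require_every_species=False).members)
        strict = set(core_members(t, meta, prevalence=0.5).members)
        assert hi <= lo
        assert strict <= lo


class TestCrossMarkerCore:
    def make(self, members, level="phylum", marker="V12"):
        from gutcore.core import CoreSet

        return CoreSet(
            level=level, members=list(members), prevalence=0.8,
            n_individuals=25, require_every_species=True, scope="wild",
            marker=marker,
        )

    def test_identity_disjoint_and_partial(self):
        a = self.make(["Firmicutes", "Fusobacteria", "TM7"])
        b = self.make(["Firmicutes", "Fusobacteria"], marker="V34")
        assert cross_marker_core(a, a).members == sorted(a.members)
        assert cross_marker_core(a, self.make([], marker="V34")).members == []
        both = cross_marker_core(a, b)
        assert both.members == ["Firmicutes", "Fusobacteria"]
        assert both.cross_marker

    def test_unassigned_names_never_match(self):
        a = self.make(["unassigned", "Firmicutes"])
        b = self.make(["unassigned", "Firmicutes"], marker="V34")
        assert cross_marker_core(a, b).members == ["Firmicutes"]

    def test_otu_level_rejected(self):
        with pytest.raises(ValueError, match="taxa"):
            cross_marker_core(self.make(["x"], level="otu"), self.make(["x"]))


class TestRelativeCoreLength:
    def test_identical_individuals_give_one(self):
        meta = meta_for({"a": 5})
        t = table_for(meta, np.ones((5, 4)))
        assert relative_core_length(t, meta.sample_ids) == 1.0

    def test_disjoint_individuals_give_zero(self):
        meta = meta_for({"a": 4})
        t = table_for(meta, np.eye(4))
        assert relative_core_length(t, meta.sample_ids) == 0.0

    def test_worked_five_individual_table(self):
        meta = meta_for({"a": 5})
        pres = np.array(
            [
                [1, 1, 1, 0, 1, 0],
                [1, 1, 0, 0, 1, 0],
                [1, 1, 1, 0, 0, 0],
                [1, 0, 1, 1, 1, 0],
                [1, 1, 1, 0, 1, 0],
            ]
        )
        t = table_for(meta, pres)
        # occurrences: 5,4,4,1,4,0 -> need ceil(0.8*5)=4 -> 4 core of 5 observed
        assert relative_core_length(t, meta.sample_ids) == pytest.approx(4 / 5)
        oracle = _oracles.brute_relative_core_length(pres.astype(bool), range(5))
        assert relative_core_length(t, meta.sample_ids) == pytest.approx(oracle)


class TestCoreLengthPermutationTest:
    def test_identical_individuals_everywhere_give_p_one(self):
        meta = meta_for({"a": 4, "b": 4})
        t = table_for(meta, np.ones((8, 5)))
        res = core_length_permutation_test(t, meta, draw=5, permutations=50, seed_or_rng=0)
        for r in res.values():
            assert r.observed == 1.0
            assert (r.null_values == 1.0).all()
            assert r.p_value == 1.0

    def test_single_individual_species_excluded(self):
        meta = meta_for({"a": 5, "solo": 1})
        rng = np.random.default_rng(0)
        t = table_for(meta, rng.integers(0, 2, (6, 10)) + np.eye(6, 10, dtype=int))
        res = core_length_permutation_test(t, meta, draw=5, permutations=20, seed_or_rng=0)
        assert "solo" not in res
        assert "a" in res

    def test_null_matches_exhaustive_enumeration_of_six_draws(self):
        """Six pooled fish, draw five: the Monte-Carlo null can only
        take the six values of the exhaustive leave-one-out subsets."""
        meta = meta_for({"a": 3, "b": 3})
        rng = np.random.default_rng(1)
        pres = rng.integers(0, 2, (6, 12)).astype(bool)
        pres[:, 0] = True
        t = table_for(meta, pres.astype(int))
        res = core_length_permutation_test(
            t, meta, draw=5, permutations=600, seed_or_rng=2
        )
        exact = np.array(_oracles.exhaustive_core_length_null(pres, 5))
        null = res["a"].null_values
        # every Monte-Carlo value is one of the six exhaustive subset values
        assert all(np.any(np.abs(exact - v) < 1e-12) for v in null)
        # and the Monte-Carlo p matches the exhaustive p within 2 MC SE
        obs = res["a"].observed
        p_exact = (np.sum(exact >= obs - 1e-12) + 1) / (len(exact) + 1)
        se = np.sqrt(p_exact * (1 - p_exact) / 600)
        assert abs(res["a"].p_value - p_exact) <= 2 * se + 2 / 600

    def test_planted_conspecific_cores_rejected_against_null(self, default_dataset):
        tables, _, _, meta, _ = default_dataset
        res = core_length_permutation_test(
            tables["V12"], meta, draw=5, permutations=500, seed_or_rng=3
        )
        five_member = [r for r in res.values() if r.n_conspecifics == 5]
        assert all(r.p_value < 0.05 for r in five_member)


class TestSharedOtuProportions:
    def test_identical_and_disjoint_pairs(self):
        meta = meta_for({"a": 2, "b": 2})
        pres = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]])
        t = table_for(meta, pres)
        res = shared_otu_proportions(t, meta)
        pairs = res.pairs.set_index(["sample_a", "sample_b"])
        assert pairs.at[("a_0", "a_1"), "shared_fraction"] == 1.0
        assert pairs.at[("a_0", "b_0"), "shared_fraction"] == 0.0

    def test_planted_cores_make_intra_exceed_inter(self, default_dataset):
        tables, _, _, meta, _ = default_dataset
        res = shared_otu_proportions(tables["V12"], meta)
        assert np.median(res.intra) > np.median(res.inter)
        assert res.test.p_value < 0.01

    def test_tribe_scope_filters_pairs(self, default_dataset):
        tables, _, _, meta, _ = default_dataset
        res = shared_otu_proportions(tables["V12"], meta, scope_tribe="Perissodini")
        samples = set(res.pairs["sample_a"]) | set(res.pairs["sample_b"])
        assert not any(s.startswith("Astbur") for s in samples)
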
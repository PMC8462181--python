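"""Diversity metrics against hand computations and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hiddendiv as hd
from hiddendiv.diversity import TreeIndex

from conftest import make_tree


class TestRichnessAbundance:
    def test_rows(self, toy_comm):
        assert hd.richness(toy_comm, 0) == 2 and hd.total_abundance(toy_comm, 0) == 3
        empty = hd.CommunityMatrix(np.zeros((1, 3), dtype=int), ("s",), ("A", "B", "C"))
        assert hd.richness(empty, 0) == 0 and hd.total_abundance(empty, 0) == 0

    def test_total_individuals_is_matrix_sum(self, toy_comm):
        total = sum(hd.total_abundance(toy_comm, i) for i in range(toy_comm.n_sites))
        assert total == toy_comm.abundance.sum()


class TestGower:
    def test_identical_rows_distance_zero(self):
        tm = hd.TraitMatrix(pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [0, 0, 1]},
                                         index=["X", "Y", "Z"]), binary=("b",))
        assert hd.gower_distance(tm).values[0, 1] == 0.0

    def test_single_binary_mismatch_is_one_over_t(self):
        tm = hd.TraitMatrix(
            pd.DataFrame({"b0": [1, 1], "b1": [0, 1], "b2": [1, 1], "b3": [0, 0]},
                         index=["X", "Y"]),
            binary=("b0", "b1", "b2", "b3"),
        )
        assert hd.gower_distance(tm).values[0, 1] == pytest.approx(1 / 4)

    def test_three_species_hand_matrix(self, toy_traits):
        sub = hd.TraitMatrix(toy_traits.data.loc[["A", "B", "C"]], binary=("spots",))
        got = hd.gower_distance(sub).values
        # size range 2: |1-2|/2, |1-3|/2, |2-3|/2; spots mismatches 1,1,0
        expected = np.array([
            [0.0, (0.5 + 1) / 2, (1.0 + 1) / 2],
            [(0.5 + 1) / 2, 0.0, (0.5 + 0) / 2],
            [(1.0 + 1) / 2, (0.5 + 0) / 2, 0.0],
        ])
        np.testing.assert_allclose(got, expected)

    def test_zero_range_trait_dropped_with_warning(self):
        tm = hd.TraitMatrix(pd.DataFrame({"flat": [2.0, 2.0], "a": [0.0, 1.0]},
                                         index=["X", "Y"]))
        with pytest.warns(UserWarning):
            d = hd.gower_distance(tm)
        assert d.values[0, 1] == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_identity_and_range(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        df = pd.DataFrame({
            "c1": rng.normal(size=n), "c2": rng.normal(size=n),
            "b": rng.integers(0, 2, size=n),
        }, index=[f"t{i}" for i in range(n)])
        d = hd.gower_distance(hd.TraitMatrix(df, binary=("b",))).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1 + 1e-12


class TestUPGMA:
    def test_two_species_cherry(self):
        d = hd.DistanceMatrix(np.array([[0, 0.6], [0.6, 0]]), ("A", "B"))
        tree = hd.functional_dendrogram(d)
        ti = TreeIndex(tree)
        assert ti.pd(["A", "B"]) == pytest.approx(0.6)

    def test_ultrametric_input_is_fixed_point(self, toy_tree):
        d = hd.patristic_distance_matrix(make_tree("((A:1,B:1):1,(C:2,D:2):0.5);"),
                                         ["A", "B", "C", "D"])
        # make it ultrametric first: ((A:1,B:1):1.5,(C:2.5,D:2.5):0);  depth 2.5
        du = hd.DistanceMatrix(np.array([
            [0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 5], [5, 5, 5, 0]
        ], dtype=float), ("A", "B", "C", "D"))
        tree = hd.functional_dendrogram(du)
        got = hd.patristic_distance_matrix(tree, ["A", "B", "C", "D"]).values
        np.testing.assert_allclose(got, du.values, atol=1e-12)

    def test_four_species_hand_trace(self):
        # UPGMA by hand: merge (A,B) at 2; then C at mean(6,8)=7; then D at mean(9,11,13)=11
        d = hd.DistanceMatrix(np.array([
            [0, 2, 6, 9], [2, 0, 8, 11], [6, 8, 0, 13], [9, 11, 13, 0]
        ], dtype=float), ("A", "B", "C", "D"))
        tree = hd.functional_dendrogram(d)
        coph = hd.patristic_distance_matrix(tree, ["A", "B", "C", "D"]).values
        np.testing.assert_allclose(coph[0, 1], 2.0)
        np.testing.assert_allclose(coph[0, 2], 7.0)
        np.testing.assert_allclose(coph[0, 3], 11.0)
        np.testing.assert_allclose(coph[2, 3], 11.0)


class TestFaithPD:
    def test_full_community_is_total_branch_length(self, toy_tree, toy_comm):
        assert hd.faith_pd(toy_comm, 1, toy_tree) == pytest.approx(7.5)

    def test_single_species_is_root_path(self, toy_tree):
        comm = hd.CommunityMatrix(np.array([[0, 0, 1, 0]]), ("s",), ("A", "B", "C", "D"))
        assert hd.faith_pd(comm, 0, toy_tree) == pytest.approx(2.5)  # 2 + 0.5

    def test_empty_site_is_zero(self, toy_tree):
        comm = hd.CommunityMatrix(np.zeros((1, 4), dtype=int), ("s",),
                                  ("A", "B", "C", "D"))
        assert hd.faith_pd(comm, 0, toy_tree) == 0.0

    def test_subset_matches_edge_enumeration_oracle(self, toy_tree):
        """PD of every species subset equals a brute-force path enumeration."""
        # oracle: edges on root-to-tip paths, enumerated from the newick by hand:
        # A:[eA(1), eAB(1)], B:[eB(1), eAB(1)], C:[eC(2), eCD(0.5)], D:[eD(2), eCD(0.5)]
        edge_sets = {
            "A": {"eA", "eAB"}, "B": {"eB", "eAB"},
            "C": {"eC", "eCD"}, "D": {"eD", "eCD"},
        }
        lengths = {"eA": 1, "eB": 1, "eAB": 1, "eC": 2, "eD": 2, "eCD": 0.5}
        species = ("A", "B", "C", "D")
        ti = TreeIndex(toy_tree)
        for r in range(1, 5):
            for subset in itertools.combinations(species, r):
                union = set().union(*(edge_sets[s] for s in subset))
                expected = sum(lengths[e] for e in union)
                row = np.array([[1 if s in subset else 0 for s in species]])
                comm = hd.CommunityMatrix(row, ("s",), species)
                assert hd.faith_pd(comm, 0, ti) == pytest.approx(expected), subset

    def test_monotone_in_species_additions(self, toy_tree):
        species = ("A", "B", "C", "D")
        ti = TreeIndex(toy_tree)
        rng = np.random.default_rng(4)
        for _ in range(20):
            row = rng.integers(0, 2, size=4)
            extra = row.copy()
            zero_idx = np.flatnonzero(extra == 0)
            if len(zero_idx) == 0:
                continue
            extra[rng.choice(zero_idx)] = 1
            c1 = hd.CommunityMatrix(row[None], ("s",), species)
            c2 = hd.CommunityMatrix(extra[None], ("s",), species)
            assert hd.faith_pd(c2, 0, ti) >= hd.faith_pd(c1, 0, ti) - 1e-12

    def test_missing_species_raises(self, toy_tree):
        comm = hd.CommunityMatrix(np.array([[1]]), ("s",), ("Z",))
        with pytest.raises(KeyError):
            hd.faith_pd(comm, 0, toy_tree)


class TestMPD:
    dm = hd.DistanceMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]),
                           ("A", "B", "C"))

    def test_two_species_any_weights(self):
        comm = hd.CommunityMatrix(np.array([[4, 1, 0]]), ("s",), ("A", "B", "C"))
        assert hd.mpd(comm, 0, self.dm, weighted=False) == 1.0
        assert hd.mpd(comm, 0, self.dm, weighted=True) == 1.0

    def test_equidistant_species(self):
        d = hd.DistanceMatrix(np.full((3, 3), 0.7) - 0.7 * np.eye(3), ("A", "B", "C"))
        comm = hd.CommunityMatrix(np.array([[5, 1, 2]]), ("s",), ("A", "B", "C"))
        assert hd.mpd(comm, 0, d, weighted=True) == pytest.approx(0.7)
        assert hd.mpd(comm, 0, d, weighted=False) == pytest.approx(0.7)

    def test_weighted_hand_example(self):
        comm = hd.CommunityMatrix(np.array([[1, 2, 3]]), ("s",), ("A", "B", "C"))
        assert hd.mpd(comm, 0, self.dm, weighted=True) == pytest.approx(26 / 11)

    def test_fewer_than_two_species_undefined(self):
        comm = hd.CommunityMatrix(np.array([[0, 2, 0]]), ("s",), ("A", "B", "C"))
        assert math.isnan(hd.mpd(comm, 0, self.dm))

    def test_invariant_to_species_ordering(self):
        comm = hd.CommunityMatrix(np.array([[1, 2, 3]]), ("s",), ("A", "B", "C"))
        perm = ["C", "A", "B"]
        comm_p = hd.CommunityMatrix(np.array([[3, 1, 2]]), ("s",), tuple(perm))
        assert hd.mpd(comm_p, 0, self.dm.reorder(perm), weighted=True) == pytest.approx(
            hd.mpd(comm, 0, self.dm, weighted=True)
        )


class TestSES:
    def test_richness_invariant_under_tip_shuffle(self, toy_comm):
        dm = hd.DistanceMatrix(np.ones((4, 4)) - np.eye(4), toy_comm.species)
        null = hd.NullModelSpec("tip_shuffle", n_perm=30, seed=2)
        res = hd.ses(lambda c, i, s: hd.richness(c, i), toy_comm, dm, null)
        for r in res:
            assert r.undefined and math.isnan(r.ses)
            assert r.observed == r.null_mean  # difference is exactly zero

    def test_sampled_matches_exhaustive_permutations(self, toy_tree):
        """Large-sample tip-shuffle SES converges to the exhaustive 4! answer."""
        species = ("A", "B", "C", "D")
        comm = hd.CommunityMatrix(np.array([[1, 0, 2, 0]]), ("s",), species)
        ti = TreeIndex(toy_tree)

        vals = []
        for perm in itertools.permutations(species):
            mapping = dict(zip(species, perm))
            vals.append(ti.relabelled(mapping).pd(["A", "C"]))
        vals = np.array(vals)
        exact_mean, exact_sd = vals.mean(), vals.std(ddof=1)
        obs = ti.pd(["A", "C"])
        exact_ses = (obs - exact_mean) / exact_sd

        null = hd.NullModelSpec("tip_shuffle", n_perm=6000, seed=7)
        res = hd.ses(hd.faith_pd, comm, ti, null)[0]
        mc_se = exact_sd / math.sqrt(null.n_perm)
        assert res.null_mean == pytest.approx(exact_mean, abs=4 * mc_se)
        assert res.ses == pytest.approx(exact_ses, abs=0.15)

    def test_sign_convention_positive_means_overdispersed(self):
        """Observed metric above the null mean gives a positive SES."""
        dm = hd.DistanceMatrix(
            np.array([[0, 10, 1], [10, 0, 1], [1, 1, 0.0]]), ("A", "B", "C")
        )
        comm = hd.CommunityMatrix(np.array([[1, 1, 0]]), ("s",), ("A", "B", "C"))
        null = hd.NullModelSpec("tip_shuffle", n_perm=200, seed=3)
        res = hd.ses(hd.mpd, comm, dm, null)[0]
        assert res.observed == 10.0
        assert res.ses > 0

    def test_site_shuffle_permutes_rows(self, toy_comm):
        null = hd.NullModelSpec("site_shuffle", n_perm=400, seed=5)
        res = hd.ses(lambda c, i, s: hd.richness(c, i), toy_comm, None, null)
        # null distribution per site = richness of a random row: mean ~ (2+4+2)/3
        for r in res:
            assert r.null_mean == pytest.approx(8 / 3, abs=0.15)

    def test_species_shuffle_preserves_row_multisets(self, toy_comm):
        null = hd.NullModelSpec("species_shuffle", n_perm=50, seed=6)
        res = hd.ses(lambda c, i, s: hd.total_abundance(c, i), toy_comm, None, null)
        for r in res:  # abundance is invariant to permuting species identities
            assert r.observed == r.null_mean

    def test_seed_reproducibility(self, toy_comm, toy_tree):
        null = hd.NullModelSpec("tip_shuffle", n_perm=25, seed=11)
        a = hd.ses(hd.faith_pd, toy_comm, TreeIndex(toy_tree), null)
        b = hd.ses(hd.faith_pd, toy_comm, TreeIndex(toy_tree), null)
        np.testing.assert_array_equal([r.ses for r in a], [r.ses for r in b])
        np.testing.assert_array_equal([r.null_mean for r in a], [r.null_mean for r in b])
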
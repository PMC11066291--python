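"""O/E edge statistics, distances, neighbor joining, consensus splits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from repeatphylo import readgraph, repnet, trees


def graph_of(n, edges, species):
    return readgraph.ReadGraph(
        ids=[f"r{i}" for i in range(n)],
        species=np.asarray(species, dtype=object),
        edges_u=np.array([e[0] for e in edges], dtype=np.int64),
        edges_v=np.array([e[1] for e in edges], dtype=np.int64),
        scores=np.ones(len(edges), dtype=np.int64),
        k=13,
        min_shared=1,
    )


class TestObservedExpected:
    def test_complete_graph_two_plus_two(self):
        # K4 on species (x,x,y,y): 6 edges, 4 inter-species;
        # expected inter = 6 * (2*2)/6 = 4 -> ratio 1
        edges = list(itertools.combinations(range(4), 2))
        g = graph_of(4, edges, ["x", "x", "y", "y"])
        m = repnet.observed_expected(g)
        assert m.observed.loc["x", "y"] == 4
        assert m.expected.loc["x", "y"] == pytest.approx(4.0)
        assert m.ratio.loc["x", "y"] == pytest.approx(1.0)
        assert m.ratio.loc["x", "x"] == pytest.approx(1.0)

    def test_no_interspecies_edges_zero_offdiagonal(self):
        g = graph_of(4, [(0, 1), (2, 3)], ["x", "x", "y", "y"])
        m = repnet.observed_expected(g)
        assert m.ratio.loc["x", "y"] == 0.0
        assert m.observed.loc["x", "y"] == 0

    def test_single_species_cluster_is_one_by_one(self):
        g = graph_of(3, [(0, 1), (1, 2)], ["x", "x", "x"])
        m = repnet.observed_expected(g)
        assert m.ratio.shape == (1, 1)

    def test_empty_graph_rejected(self):
        g = graph_of(0, [], [])
        with pytest.raises(ValueError):
            repnet.observed_expected(g)


class TestDropEdgeless:
    def _mat(self, obs_off, species=("x", "y")):
        idx = pd.Index(species)
        O = pd.DataFrame([[3.0, obs_off], [obs_off, 2.0]], index=idx, columns=idx)
        R = O.copy()
        return repnet.EdgeStatMatrix(
            ratio=R, observed=O, expected=O.copy(),
            n_reads=pd.Series(2, index=idx), e_total=5,
        )

    def test_edgeless_dropped_connected_kept(self):
        out = repnet.drop_edgeless([self._mat(0.0), self._mat(1.0)])
        assert len(out) == 1

    def test_empty_input_empty_output(self):
        assert repnet.drop_edgeless([]) == []

    def test_outgroup_removed_before_test(self):
        idx = pd.Index(["in1", "in2", "og"])
        O = pd.DataFrame(0.0, index=idx, columns=idx)
        O.loc["in1", "og"] = O.loc["og", "in1"] = 4.0  # only outgroup connections
        m = repnet.EdgeStatMatrix(ratio=O.copy(), observed=O, expected=O.copy(),
                                  n_reads=pd.Series(2, index=idx), e_total=4)
        assert repnet.drop_edgeless([m], outgroup=["og"]) == []


class TestToDistance:
    def _mat(self):
        idx = pd.Index(["x", "y", "z"])
        R = pd.DataFrame(
            [[5.0, 2.0, 0.0], [2.0, 4.0, 1.0], [0.0, 1.0, 6.0]],
            index=idx, columns=idx,
        )
        return repnet.EdgeStatMatrix(ratio=R, observed=R.copy(), expected=R.copy(),
                                     n_reads=pd.Series(2, index=idx), e_total=9)

    def test_extremes_map_to_zero_and_one(self):
        D = repnet.to_distance(self._mat())
        assert D.loc["x", "y"] == pytest.approx(0.0)  # the maximal-ratio pair
        assert D.loc["x", "z"] == pytest.approx(1.0)  # zero-ratio pair

    def test_symmetric_zero_diagonal(self):
        D = repnet.to_distance(self._mat())
        assert np.allclose(D.to_numpy(), D.to_numpy().T)
        assert np.allclose(np.diag(D.to_numpy()), 0.0)

    def test_all_zero_offdiagonal_rejected(self):
        idx = pd.Index(["x", "y"])
        R = pd.DataFrame([[3.0, 0.0], [0.0, 3.0]], index=idx, columns=idx)
        m = repnet.EdgeStatMatrix(ratio=R, observed=R.copy(), expected=R.copy(),
                                  n_reads=pd.Series(2, index=idx), e_total=3)
        with pytest.raises(ValueError):
            repnet.to_distance(m)


class TestNeighborJoining:
    def test_three_taxa_branch_lengths_solve_linear_system(self):
        idx = pd.Index(["a", "b", "c"])
        D = pd.DataFrame(
            [[0.0, 0.5, 0.9], [0.5, 0.0, 0.8], [0.9, 0.8, 0.0]],
            index=idx, columns=idx,
        )
        tree = repnet.neighbor_joining(D)
        got = trees.path_distance_matrix(tree)
        assert np.allclose(got.loc[idx, idx].to_numpy(), D.to_numpy(), atol=1e-10)

    def test_additive_matrices_recovered_exactly(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 7))
            true = trees.random_unrooted_tree(n, rng)
            D = trees.path_distance_matrix(true)
            nj = repnet.neighbor_joining(D)
            got = trees.path_distance_matrix(nj)
            assert np.allclose(got.loc[D.index, D.columns].to_numpy(), D.to_numpy(), atol=1e-8)
            assert (
                repnet.splits_of(nj).nontrivial().keys()
                == repnet.splits_of(true).nontrivial().keys()
            )

    def test_topology_agrees_with_skbio(self, rng):
        """Independent cross-check: scikit-bio's NJ finds the same topology."""
        import io

        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(5):
            true = trees.random_unrooted_tree(6, rng)
            D = trees.path_distance_matrix(true)
            ours = repnet.neighbor_joining(D)
            sk_tree = sk_nj(SkDM(D.to_numpy(), ids=list(D.index)))
            sk_dendro = trees.tree_from_newick(str(sk_tree))
            sk_dendro.is_rooted = False
            assert (
                repnet.splits_of(ours).nontrivial().keys()
                == repnet.splits_of(sk_dendro).nontrivial().keys()
            )

    def test_taxon_order_invariance(self, rng):
        true = trees.random_unrooted_tree(6, rng)
        D = trees.path_distance_matrix(true)
        perm = list(D.index)[::-1]
        t1 = repnet.neighbor_joining(D)
        t2 = repnet.neighbor_joining(D.loc[perm, perm])
        assert repnet.splits_of(t1).splits.keys() == repnet.splits_of(t2).splits.keys()

    def test_fewer_than_three_taxa_rejected(self):
        idx = pd.Index(["a", "b"])
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=idx, columns=idx)
        with pytest.raises(ValueError):
            repnet.neighbor_joining(D)


class TestSplits:
    def test_quartet_has_one_nontrivial_split(self):
        t = trees.tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t.is_rooted = False
        ss = repnet.splits_of(t)
        assert len(ss.nontrivial()) == 1
        assert frozenset({"c", "d"}) in ss

    def test_star_tree_no_nontrivial_splits(self):
        t = trees.tree_from_newick("(a:1,b:1,c:1,d:1,e:1);")
        t.is_rooted = False
        assert repnet.splits_of(t).nontrivial() == {}

    def test_binary_tree_has_n_minus_three_nontrivial_splits(self, rng):
        for n in (4, 5, 6, 8):
            t = trees.random_unrooted_tree(n, rng)
            assert len(repnet.splits_of(t).nontrivial()) == n - 3


class TestConsensus:
    def _trees(self, newicks):
        out = []
        for nwk in newicks:
            t = trees.tree_from_newick(nwk)
            t.is_rooted = False
            out.append(t)
        return out

    def test_identical_trees_all_splits_at_one(self):
        ts = self._trees(["((a:1,b:1):1,(c:1,d:1):1);"] * 5)
        cons = repnet.consensus(ts)
        assert cons.frequency({"c", "d"}) == 1.0

    def test_rare_split_excluded_boundary_split_included(self):
        quartet = "((a:1,b:1):1,(c:1,d:1):1);"
        other = "((a:1,c:1):1,(b:1,d:1):1);"
        ts = self._trees([quartet] * 1 + [other] * 19)  # 5% < 10%
        cons = repnet.consensus(ts, min_freq=0.10)
        assert frozenset({"c", "d"}) not in cons
        ts = self._trees([quartet] * 2 + [other] * 18)  # exactly 10%
        cons = repnet.consensus(ts, min_freq=0.10)
        assert cons.frequency({"c", "d"}) == pytest.approx(0.10)

    def test_tree_order_invariance(self, rng):
        ts = [trees.random_unrooted_tree(5, rng) for _ in range(8)]
        # same taxon labels by construction
        a = repnet.consensus(ts, min_freq=0.10)
        b = repnet.consensus(ts[::-1], min_freq=0.10)
        assert a.splits == b.splits

    def test_mismatched_taxa_rejected(self):
        t1 = self._trees(["((a:1,b:1):1,(c:1,d:1):1);"])[0]
        t2 = self._trees(["((a:1,b:1):1,(c:1,e:1):1);"])[0]
        with pytest.raises(ValueError):
            repnet.consensus([t1, t2])


class TestSplitsNexus:
    def test_round_trip_exact(self, tmp_path, rng):
        ts = [trees.random_unrooted_tree(6, rng) for _ in range(5)]
        cons = repnet.consensus(ts, min_freq=0.10)
        path = tmp_path / "splits.nex"
        repnet.write_splits_nexus(cons, path)
        back = repnet.read_splits_nexus(path)
        assert back.taxa == cons.taxa
        assert back.splits == cons.splits

    def test_empty_split_set_valid(self, tmp_path):
        ss = repnet.SplitSet(taxa=("a", "b", "c"), splits={})
        path = tmp_path / "empty.nex"
        repnet.write_splits_nexus(ss, path)
        back = repnet.read_splits_nexus(path)
        assert back.splits == {}

    def test_taxa_with_spaces_quoted(self, tmp_path):
        ss = repnet.SplitSet(
            taxa=("sp one", "sp two", "sp three"),
            splits={frozenset({"sp two"}): 1.0},
        )
        path = tmp_path / "quoted.nex"
        repnet.write_splits_nexus(ss, path)
        back = repnet.read_splits_nexus(path)
        assert back.taxa == ss.taxa
        assert back.splits == ss.splits


def test_clade_structured_sharing_recovers_clades(study_result):
    """The consensus split network contains every true clade bipartition."""
    for side in study_result.true_clade_splits():
        assert study_result.splits.frequency(side) >= 0.5
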
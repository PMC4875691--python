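import dendropy
import numpy as np
import pytest

from bamphy._errors import ArgumentError, DataError
from bamphy.align import Alignment
from bamphy.simulate import DEFAULT_TAXA, evolve_sequences, make_species_tree
from bamphy.trees import (
    DistanceMatrix,
    bootstrap_support,
    k2p_distance_matrix,
    majority_consensus,
    neighbor_joining,
    tree_bipartitions,
)

from _oracles import (
    all_unrooted_topologies,
    bipartitions_of,
    random_binary_tree_matrix,
    to_newick,
)


def dm(labels, d):
    d = np.asarray(d, dtype=float)
    z = np.zeros_like(d)
    return DistanceMatrix(list(labels), d, z, z)


class TestK2PDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        m = k2p_distance_matrix(aln)
        assert m.d[0, 1] == 0.0 and m.P[0, 1] == 0.0 and m.Q[0, 1] == 0.0

    def test_closed_form_value(self):
        # 20 columns: 2 transitions (P=0.1), 1 transversion (Q=0.05)
        a = "ACGTACGTACGTACGTACGT"
        b = "GCGTACGCACGTACGTACGA"  # A->G, T->C transitions; T->A transversion
        aln = Alignment(["a", "b"], [a, b])
        m = k2p_distance_matrix(aln)
        assert m.P[0, 1] == pytest.approx(0.10)
        assert m.Q[0, 1] == pytest.approx(0.05)
        expected = -0.5 * np.log(0.75 * np.sqrt(0.9))
        assert m.d[0, 1] == pytest.approx(expected, abs=1e-12)
        assert m.d[0, 1] == pytest.approx(0.1702, abs=5e-4)

    def test_monotone_in_transition_proportion(self):
        # numeric sweep of the closed form at fixed Q
        q = 0.05
        ds = [
            -0.5 * np.log((1 - 2 * p - q) * np.sqrt(1 - 2 * q))
            for p in np.linspace(0.0, 0.4, 30)
        ]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_gapped_columns_excluded_pairwise(self):
        aln = Alignment(["a", "b"], ["ACGT--GT", "ACGTAC-T"])
        m = k2p_distance_matrix(aln)
        assert m.d[0, 1] == 0.0  # only shared ungapped columns compared

    def test_saturation_capped_with_warning(self):
        aln = Alignment(["a", "b"], ["ACGTACGTACGT", "GTACGTACGTAC"])
        with pytest.warns(UserWarning, match="saturated"):
            m = k2p_distance_matrix(aln)
        assert m.d[0, 1] == 10.0

    def test_no_shared_columns_rejected(self):
        aln = Alignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(DataError):
            k2p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.4, 0.6, 0.8
        tree = neighbor_joining(dm("ABC", [[0, d12, d13], [d12, 0, d23], [d13, 0.8, 0]]))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["B"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["C"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ArgumentError):
            neighbor_joining(dm("AB", [[0, 1], [1, 0]]))

    def test_additive_matrix_recovery(self, rng):
        """On additive matrices NJ recovers the generating topology with
        exact branch lengths (20 trees here; 100 in the acceptance run)."""
        labels = ["A", "B", "C", "D", "E", "F"]
        for _ in range(20):
            D = random_binary_tree_matrix(labels, rng)
            tree = neighbor_joining(dm(labels, D))
            pdm = tree.phylogenetic_distance_matrix()
            tns = tree.taxon_namespace
            for i in range(6):
                for j in range(i + 1, 6):
                    got = pdm.distance(
                        tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                    )
                    assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_taxon_order_permutation_invariant(self, rng):
        labels = ["A", "B", "C", "D", "E", "F"]
        D = random_binary_tree_matrix(labels, rng)
        t_ref = neighbor_joining(dm(labels, D))
        perm = rng.permutation(6)
        D2 = D[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        t_perm = neighbor_joining(dm(labels2, D2))
        assert tree_bipartitions(t_ref) == tree_bipartitions(t_perm)

    def test_negative_estimates_clamped(self):
        # a strongly non-additive matrix that would produce negative lengths
        D = [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]]
        tree = neighbor_joining(dm("ABCD", D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBipartitions:
    def test_agrees_with_exhaustive_enumeration_small_trees(self):
        """dendropy-backed bipartition extraction equals structural
        enumeration on every unrooted topology with 5 and 6 leaves."""
        for labels in (list("ABCDE"), list("ABCDEF")):
            for topo in all_unrooted_topologies(labels):
                nwk = to_newick(topo) + ";"
                tree = dendropy.Tree.get(data=nwk, schema="newick")
                assert tree_bipartitions(tree) == bipartitions_of(topo)


class TestBootstrap:
    def test_unambiguous_signal_gives_full_support(self):
        rows = {
            "A": "A" * 60 + "C" * 60,
            "B": "A" * 60 + "C" * 60,
            "C": "C" * 60 + "A" * 60,
            "D": "C" * 60 + "G" * 60,
        }
        aln = Alignment(list(rows), list(rows.values()))
        result = bootstrap_support(aln, n_replicates=100, seed=1)
        assert result.supports and all(v == 1.0 for v in result.supports.values())

    def test_single_replicate_supports_are_zero_or_one(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        result = bootstrap_support(aln, n_replicates=1, seed=2)
        assert set(result.supports.values()) <= {0.0, 1.0}

    def test_fixed_seed_is_deterministic(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        a = bootstrap_support(aln, n_replicates=50, seed=3)
        b = bootstrap_support(aln, n_replicates=50, seed=3)
        assert a.supports == b.supports

    def test_support_for_true_clades_grows_with_length(self):
        tree = make_species_tree(DEFAULT_TAXA[:6])
        means = []
        for length in (100, 1_000, 10_000):
            leaves = evolve_sequences(tree, length, scale=0.02, seed=9)
            aln = Alignment(*map(list, zip(*sorted(leaves.items()))))
            result = bootstrap_support(aln, n_replicates=100, seed=10)
            means.append(np.mean(list(result.supports.values())))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > 0.99


class TestMajorityConsensus:
    def _trees(self, *newicks, tns=None):
        tns = tns or dendropy.TaxonNamespace()
        return [
            dendropy.Tree.get(data=n, schema="newick", taxon_namespace=tns)
            for n in newicks
        ]

    def test_identical_trees_reproduce_topology_at_full_frequency(self):
        trees = self._trees(*["((A,B),(C,(D,E)));"] * 3)
        cons = majority_consensus(trees)
        assert tree_bipartitions(cons) == tree_bipartitions(trees[0])
        labels = [
            nd.label for nd in cons.preorder_internal_node_iter() if nd.label
        ]
        assert all(lbl == "1.000" for lbl in labels)

    def test_two_thirds_majority_keeps_disputed_split(self):
        trees = self._trees(
            "((A,B),(C,(D,E)));",
            "((A,B),(C,(D,E)));",
            "((A,C),(B,(D,E)));",  # one NNI away
        )
        cons = majority_consensus(trees)
        bips = tree_bipartitions(cons)
        assert frozenset({"D", "E"}) in bips  # 3/3
        assert frozenset({"C", "D", "E"}) in bips  # 2/3 (= AB split)

    def test_strictly_greater_than_threshold(self):
        trees = self._trees(
            "((A,B),(C,(D,E)));",
            "((A,C),(B,(D,E)));",
        )
        cons = majority_consensus(trees)  # AB split at exactly 0.5: dropped
        assert frozenset({"C", "D", "E"}) not in tree_bipartitions(cons)
        assert frozenset({"D", "E"}) in tree_bipartitions(cons)

    def test_idempotent_on_single_tree(self):
        (tree,) = self._trees("((A,B),(C,(D,E)));")
        once = majority_consensus([tree])
        twice = majority_consensus([once])
        assert tree_bipartitions(once) == tree_bipartitions(twice)

    def test_leaf_set_mismatch_rejected(self):
        trees = self._trees("((A,B),(C,D));", "((A,B),(C,E));")
        with pytest.raises(DataError):
            majority_consensus(trees)

    def test_matches_dendropy_consensus_on_random_trees(self, rng):
        """Independent route: dendropy's own consensus machinery agrees on
        the retained bipartition set (strict-majority case, no exact-50 %
        splits)."""
        labels = list("ABCDEFG")
        for trial in range(10):
            newicks = []
            for _ in range(5):
                topo = all_unrooted_topologies(labels)[
                    int(rng.integers(0, 945))
                ]
                newicks.append(to_newick(topo) + ";")
            tns = dendropy.TaxonNamespace()
            trees = dendropy.TreeList(taxon_namespace=tns)
            for n in newicks:
                trees.append(
                    dendropy.Tree.get(data=n, schema="newick", taxon_namespace=tns)
                )
            ours = majority_consensus(list(trees), threshold=0.5)
            theirs = trees.consensus(min_freq=0.5 + 1e-9)
            assert tree_bipartitions(ours) == tree_bipartitions(theirs)
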
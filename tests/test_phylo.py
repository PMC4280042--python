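"""Indel-block distances, NJ correctness, bootstrap, monophyly queries."""
import dendropy
import numpy as np
import pytest

from satevo.phylo import (
    DistanceMatrix,
    bootstrap_support,
    from_newick,
    indel_block_distance,
    is_monophyletic,
    neighbor_joining,
    robinson_foulds,
    root_at_outgroup_ancestor,
    to_newick,
)


def random_additive_case(rng, n_taxa):
    """A random binary tree and the distance matrix it induces."""
    labels = [f"t{i}" for i in range(n_taxa)]

    def build(labs):
        if len(labs) == 1:
            return f"{labs[0]}:{rng.uniform(0.1, 1.0):.6f}"
        k = int(rng.integers(1, len(labs)))
        return f"({build(labs[:k])},{build(labs[k:])}):{rng.uniform(0.1, 1.0):.6f}"

    newick = f"({build(labels[:1])},{build(labels[1:])});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return tree, DistanceMatrix(labels, mat)


# ---------------------------------------------------------------- distances
class TestIndelBlockDistance:
    def test_identical_rows_zero(self):
        dm = indel_block_distance({"a": "ACGT", "b": "ACGT"})
        assert dm.matrix[0, 1] == 0.0

    def test_single_gap_counts_one_event(self):
        dm = indel_block_distance({"a": "ACGT", "b": "A-GT"})
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_gap_run_collapses_to_one_event(self):
        dm = indel_block_distance({"a": "AC--T", "b": "ACGGT"})
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_run_length_invariance(self):
        short = indel_block_distance({"a": "AAC-TT", "b": "AACGTT"}).matrix[0, 1]
        long = indel_block_distance({"a": "AAC----TT", "b": "AACGGGGTT"}).matrix[0, 1]
        assert short == long

    def test_both_gap_columns_skipped(self):
        dm = indel_block_distance({"a": "A--CGT", "b": "A--CGT"})
        assert dm.matrix[0, 1] == 0.0

    def test_bounds_and_symmetry(self, rng):
        rows = {}
        for i in range(5):
            rows[f"s{i}"] = "".join(rng.choice(list("ACGT-"), size=30))
        dm = indel_block_distance(rows)
        assert np.all(dm.matrix >= 0) and np.all(dm.matrix <= 1)
        assert np.allclose(dm.matrix, dm.matrix.T)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            indel_block_distance({"a": "ACGT", "b": "ACG"})


# ---------------------------------------------------------------- NJ
class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        #   ((A:1,B:2):1,(C:3,D:1)) as a distance matrix
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        dm = DistanceMatrix(labels, mat)
        tree = neighbor_joining(dm)
        assert is_monophyletic(tree, ["A", "B"])[0]
        assert is_monophyletic(tree, ["C", "D"])[0]
        # an additive matrix is reproduced exactly by the NJ tree
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        mat[i, j], abs=1e-9
                    )

    def test_star_matrix_zero_internal_branch(self):
        dm = DistanceMatrix(["A", "B", "C", "D"], np.full((4, 4), 2.0) - 2 * np.eye(4))
        tree = neighbor_joining(dm)
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node and not e.head_node.is_leaf() and e.head_node.parent_node
        ]
        assert all(l == pytest.approx(0.0, abs=1e-12) for l in internal)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 11))
            true_tree, dm = random_additive_case(rng, n)
            nj = neighbor_joining(dm)
            assert robinson_foulds(true_tree, nj) == 0

    def test_agrees_with_skbio_topology(self, rng):
        """Independent NJ implementation gives the same topology."""
        import io as _io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        _, dm = random_additive_case(rng, 7)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.matrix, ids=dm.labels))
        theirs_dp = from_newick(str(theirs.write(_io.StringIO()).getvalue()))
        assert robinson_foulds(ours, theirs_dp) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 1], [1, 0]])))


# ---------------------------------------------------------------- bootstrap
class TestBootstrap:
    def _clean_msa(self):
        # 60 columns separate the two clades; each taxon's private columns
        # touch only trivial bipartitions, so no conflicting signal exists
        clade_a, clade_b = "A" * 60, "C" * 60
        g = "G" * 10
        return {
            "a1": clade_a + "T" * 10 + g + g + g,
            "a2": clade_a + g + "T" * 10 + g + g,
            "b1": clade_b + g + g + "T" * 10 + g,
            "b2": clade_b + g + g + g + "T" * 10,
        }

    def test_saturated_signal_full_support(self):
        tree = bootstrap_support(self._clean_msa(), B=50, seed=3)
        supports = [
            int(nd.label)
            for nd in tree.preorder_node_iter()
            if nd.label and not nd.is_leaf()
        ]
        assert supports and all(s == 100 for s in supports)

    def test_deterministic_under_seed(self):
        t1 = bootstrap_support(self._clean_msa(), B=30, seed=11)
        t2 = bootstrap_support(self._clean_msa(), B=30, seed=11)
        assert to_newick(t1) == to_newick(t2)

    def test_identical_sequences_no_supported_bipartitions(self):
        msa = {f"s{i}": "ACGTACGT" for i in range(4)}
        tree = bootstrap_support(msa, B=10, seed=0)
        labelled = [
            nd.label for nd in tree.preorder_node_iter() if nd.label and not nd.is_leaf()
        ]
        # star-like data: any resolved bipartition has zero-length branches;
        # there is no bipartition with meaningful support
        internal = [
            e for e in tree.preorder_edge_iter()
            if e.head_node and not e.head_node.is_leaf() and e.head_node.parent_node
        ]
        assert all(e.length == pytest.approx(0.0, abs=1e-12) for e in internal)
        assert labelled == [] or all(lab is not None for lab in labelled)


# ---------------------------------------------------------------- topology
class TestMonophyly:
    def test_constructed_quartet(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, ["A", "B"])[0]
        assert not is_monophyletic(tree, ["A", "C"])[0]

    def test_singleton_is_monophyletic(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ok, node = is_monophyletic(tree, ["C"])
        assert ok and node.taxon.label == "C"

    def test_empty_or_full_set_is_error(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            is_monophyletic(tree, [])
        with pytest.raises(ValueError):
            is_monophyletic(tree, ["A", "B", "C", "D"])

    def test_newick_round_trip_preserves_structure(self, rng):
        _, dm = random_additive_case(rng, 8)
        tree = neighbor_joining(dm)
        back = from_newick(to_newick(tree))
        assert robinson_foulds(tree, back) == 0

    def test_root_at_outgroup(self):
        tree = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_at_outgroup_ancestor(tree, ["C", "D"])
        assert rooted.is_rooted
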
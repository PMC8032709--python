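"""Coded sequences, p-distances, neighbor joining and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from clonalsnv.errors import UndefinedDistanceError
from clonalsnv.genotypes import GenotypeMatrix
from clonalsnv.njtree import (
    CodedSequence,
    DistanceMatrix,
    bipartitions,
    bootstrap_supports,
    code_genotypes,
    distance_matrix,
    nj_tree,
    p_distance,
    root_with_outgroup,
)

from oracles import random_additive_tree


class TestCoding:
    def test_dosage_to_characters(self):
        m = GenotypeMatrix(pd.DataFrame([[0.0, 1.0, 2.0]], index=["s1"],
                                        columns=["a", "b", "c"]))
        seqs = code_genotypes(m, outgroup=None)
        assert seqs[0].chars == "RHA"

    def test_missing_codes_to_question_mark(self):
        m = GenotypeMatrix(pd.DataFrame([[0.0, np.nan]], index=["s1"],
                                        columns=["a", "b"]))
        assert code_genotypes(m, outgroup=None)[0].chars == "R?"

    def test_outgroup_is_all_reference(self):
        m = GenotypeMatrix(pd.DataFrame(np.ones((2, 41)),
                                        index=["s1", "s2"],
                                        columns=[f"m{i}" for i in range(41)]))
        seqs = code_genotypes(m, outgroup="PN40024")
        assert seqs[-1].name == "PN40024"
        assert seqs[-1].chars == "R" * 41


class TestPDistance:
    def test_identical_is_zero(self):
        a = CodedSequence("a", "RRHHA")
        assert p_distance(a, a) == 0.0

    def test_fraction_of_differing_sites(self):
        a = CodedSequence("a", "RRHHA")
        b = CodedSequence("b", "RRHAA")
        assert p_distance(a, b) == pytest.approx(0.2)

    def test_pairwise_deletion_of_missing(self):
        a = CodedSequence("a", "R?")
        b = CodedSequence("b", "RH")
        assert p_distance(a, b) == 0.0

    def test_symmetry(self):
        a = CodedSequence("a", "RHAR?H")
        b = CodedSequence("b", "AHRRH?")
        assert p_distance(a, b) == p_distance(b, a)

    def test_no_comparable_sites_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance(CodedSequence("a", "??"), CodedSequence("b", "RH"))


class TestNeighborJoining:
    def test_three_taxon_lengths_solved_exactly(self):
        # additive 3-taxon system: la+lb=2, la+lc=4, lb+lc=4 -> (1, 1, 3)
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(2)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(4)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(4)

    def test_recovers_random_additive_trees_exactly(self):
        """NJ is consistent on additive matrices: topology and path lengths
        must match the generating tree (n = 4..8)."""
        rng = np.random.default_rng(7)
        for n in (4, 5, 6, 7, 8):
            for _ in range(4):
                names, mat, true_splits = random_additive_tree(n, rng)
                tree = nj_tree(DistanceMatrix(names, mat))
                assert bipartitions(tree) == true_splits
                pdm = tree.phylogenetic_distance_matrix()
                taxa = {t.label: t for t in tree.taxon_namespace}
                for i in range(n):
                    for j in range(i + 1, n):
                        assert pdm.distance(taxa[names[i]], taxa[names[j]]) == \
                            pytest.approx(mat[i, j], abs=1e-9)

    def test_agrees_with_skbio_reference(self):
        """Cross-check topology against the independent scikit-bio NJ."""
        import skbio

        rng = np.random.default_rng(13)
        names, mat, _ = random_additive_tree(6, rng)
        mine = nj_tree(DistanceMatrix(names, mat))
        ref = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=names))
        ref_dendropy = __import__("dendropy").Tree.get(
            data=str(ref), schema="newick",
            taxon_namespace=mine.taxon_namespace,
        )
        assert bipartitions(mine) == bipartitions(ref_dendropy)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        names, mat, _ = random_additive_tree(6, rng)
        perm = rng.permutation(len(names))
        tree_a = nj_tree(DistanceMatrix(names, mat))
        tree_b = nj_tree(DistanceMatrix([names[i] for i in perm],
                                        mat[np.ix_(perm, perm)]))
        assert bipartitions(tree_a) == bipartitions(tree_b)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))


class TestBootstrap:
    def _two_lineage_seqs(self, n_diag=10):
        # two clean lineages with n_diag private markers each
        ar = "H" * n_diag + "R" * n_diag
        fr = "R" * n_diag + "H" * n_diag
        return [
            CodedSequence("Ar1", ar), CodedSequence("Ar2", ar),
            CodedSequence("Fr1", fr), CodedSequence("Fr2", fr),
            CodedSequence("out", "R" * (2 * n_diag)),
        ]

    def test_planted_lineage_split_strongly_supported(self):
        seqs = self._two_lineage_seqs(10)
        _, supports = bootstrap_supports(seqs, n_reps=200, seed=5)
        split = frozenset({"Fr1", "Fr2"})  # side without the anchor leaf Ar1
        assert split in supports
        assert supports[split] >= 95

    def test_same_seed_reproducible(self):
        seqs = self._two_lineage_seqs(6)
        _, s1 = bootstrap_supports(seqs, n_reps=50, seed=9)
        _, s2 = bootstrap_supports(seqs, n_reps=50, seed=9)
        assert s1 == s2

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self._two_lineage_seqs(), n_reps=0)


class TestRooting:
    def _tree(self):
        rng = np.random.default_rng(21)
        names, mat, _ = random_additive_tree(5, rng)
        return nj_tree(DistanceMatrix(names, mat))

    def test_outgroup_sister_to_rest(self):
        tree = self._tree()
        out_label = sorted(l.taxon.label for l in tree.leaf_node_iter())[0]
        rooted = root_with_outgroup(tree, out_label)
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [frozenset(l.taxon.label for l in ch.leaf_iter()) for ch in children]
        assert frozenset({out_label}) in sides

    def test_rooting_preserves_bipartitions(self):
        tree = self._tree()
        before = bipartitions(tree)
        out_label = sorted(l.taxon.label for l in tree.leaf_node_iter())[0]
        rooted = root_with_outgroup(tree, out_label)
        assert bipartitions(rooted) == before

    def test_rooting_twice_is_idempotent(self):
        tree = self._tree()
        out_label = sorted(l.taxon.label for l in tree.leaf_node_iter())[0]
        once = root_with_outgroup(tree, out_label)
        newick1 = once.as_string(schema="newick")
        twice = root_with_outgroup(once, out_label)
        assert twice.as_string(schema="newick") == newick1

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(ValueError):
            root_with_outgroup(self._tree(), "nope")
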
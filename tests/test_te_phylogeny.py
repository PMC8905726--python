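"""Distance phylogeny: pairwise-deletion distances, NJ, bootstrap, branches."""

import random

import numpy as np
import pytest

from steamerscan import te_phylogeny as tp
from steamerscan.evaluation import (
    branch_oracle_subsets,
    canonical_bipartitions,
    random_additive_tree,
)


class TestPairwiseDeletionPdist:
    def test_gap_column_excluded(self):
        dm = tp.pairwise_deletion_pdist([("a", "AC-G"), ("b", "ACTG")])
        assert dm.matrix[0, 1] == 0.0
        assert dm.compared_sites[0, 1] == 3

    def test_identical_rows_zero(self):
        dm = tp.pairwise_deletion_pdist([("a", "MKVL"), ("b", "MKVL")])
        assert dm.matrix[0, 1] == 0.0

    def test_saturation_bound(self):
        dm = tp.pairwise_deletion_pdist([("a", "AAAA"), ("b", "TTTT")])
        assert dm.matrix[0, 1] == 1.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(tp.DistanceError, match="a.*b|b.*a"):
            tp.pairwise_deletion_pdist([("a", "A--"), ("b", "-TT")])

    def test_mixed_gaps(self):
        dm = tp.pairwise_deletion_pdist([("a", "AC-GT?"), ("b", "AT-GAC")])
        # comparable: columns 0,1,3,4 -> mismatches at 1 and 4
        assert dm.compared_sites[0, 1] == 4
        assert dm.matrix[0, 1] == pytest.approx(0.5)


class TestNJ:
    def test_textbook_additive_matrix(self):
        ids = ["A", "B", "C", "D"]
        M = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = tp.nj_tree(tp.DistanceMatrix(ids, M))
        assert canonical_bipartitions(tree) == {frozenset({"A", "B"})}
        # branch lengths reproduce the additive input exactly
        out = tp.tree_distances(tree)
        assert np.allclose(out.matrix, M)
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_unique_topology(self):
        M = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = tp.nj_tree(tp.DistanceMatrix(["a", "b", "c"], M))
        assert len(tree.children) == 3
        assert {lf.name for lf in tree.leaves()} == {"a", "b", "c"}

    def test_duplicate_taxon_zero_length_edge(self):
        M = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], dtype=float
        )
        tree = tp.nj_tree(tp.DistanceMatrix(["a", "a2", "c", "d"], M))
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths["a"] == 0.0 and lengths["a2"] == 0.0

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0, 1, 2], [9, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(tp.MatrixError):
            tp.nj_tree(tp.DistanceMatrix(["a", "b", "c"], M))

    def test_exact_on_random_additive_matrices(self):
        rng = random.Random(17)
        for _ in range(50):
            true = random_additive_tree(6, rng)
            dm = tp.tree_distances(true)
            out = tp.nj_tree(dm)
            assert canonical_bipartitions(out) == canonical_bipartitions(true)
            assert np.allclose(tp.tree_distances(out).matrix, dm.matrix, atol=1e-9)

    def test_agrees_with_skbio_reference(self):
        """Cross-check topology against the scikit-bio NJ implementation."""
        import skbio

        rng = random.Random(23)
        for _ in range(10):
            true = random_additive_tree(7, rng)
            dm = tp.tree_distances(true)
            ours = tp.nj_tree(dm)
            sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.ids))
            sk_bips = set()
            n_leaves = len(dm.ids)
            full = frozenset(dm.ids)
            for node in sk.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < n_leaves - 1:
                    sk_bips.add(frozenset(min(below, full - below,
                                              key=lambda s: (len(s), tuple(sorted(s))))))
            assert canonical_bipartitions(ours) == sk_bips


class TestBootstrap:
    def _congruent_alignment(self):
        # two clearly separated pairs, long congruent signal
        return [
            ("a", "A" * 60 + "C" * 60),
            ("b", "A" * 60 + "G" * 60),
            ("c", "T" * 60 + "C" * 30 + "A" * 30),
            ("d", "T" * 60 + "G" * 30 + "T" * 30),
        ]

    def test_congruent_signal_full_support(self):
        tree = tp.bootstrap_support(self._congruent_alignment(), replicates=100, seed=1)
        supports = [n.support for n in tp.tree_bipartitions(tree).values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_column_supports_degenerate(self):
        aln = [("a", "A"), ("b", "A"), ("c", "T"), ("d", "T")]
        tree = tp.bootstrap_support(aln, replicates=50, seed=2)
        supports = {n.support for n in tp.tree_bipartitions(tree).values()}
        assert supports <= {0.0, 100.0}

    def test_deterministic_under_fixed_seed(self):
        aln = self._congruent_alignment()
        t1 = tp.bootstrap_support(aln, replicates=100, seed=7)
        t2 = tp.bootstrap_support(aln, replicates=100, seed=7)
        assert t1.newick() == t2.newick()

    def test_supports_invariant_to_taxon_order(self):
        aln = self._congruent_alignment()
        t1 = tp.bootstrap_support(aln, replicates=100, seed=3)
        t2 = tp.bootstrap_support(list(reversed(aln)), replicates=100, seed=3)
        s1 = {frozenset(bp): n.support for bp, n in tp.tree_bipartitions(t1).items()}
        s2 = {frozenset(bp): n.support for bp, n in tp.tree_bipartitions(t2).items()}
        full = frozenset(t for t, _ in aln)
        canon1 = {frozenset(min(bp, full - bp, key=lambda s: (len(s), tuple(sorted(s))))): v
                  for bp, v in s1.items()}
        canon2 = {frozenset(min(bp, full - bp, key=lambda s: (len(s), tuple(sorted(s))))): v
                  for bp, v in s2.items()}
        assert canon1 == canon2


class TestDefineBranches:
    def _supported_tree(self):
        #  ((a1,a2)95,(b1,b2)70,c) with species map: a* -> sp1/sp2, b* -> sp3
        a1 = tp.TreeNode("a1", 1)
        a2 = tp.TreeNode("a2", 1)
        b1 = tp.TreeNode("b1", 1)
        b2 = tp.TreeNode("b2", 1)
        c = tp.TreeNode("c", 1)
        pa = tp.TreeNode(length=1, support=95.0)
        pa.children = [a1, a2]
        pb = tp.TreeNode(length=1, support=70.0)
        pb.children = [b1, b2]
        root = tp.TreeNode()
        root.children = [pa, pb, c]
        return root

    def test_supported_multispecies_clade_reported(self):
        smap = {"a1": "sp1", "a2": "sp2", "b1": "sp3", "b2": "sp3", "c": "sp4"}
        groups = tp.define_branches(self._supported_tree(), smap)
        members = {g.members for g in groups}
        assert frozenset({"a1", "a2"}) in members

    def test_low_support_not_reported(self):
        smap = {"a1": "sp1", "a2": "sp2", "b1": "sp3", "b2": "sp4", "c": "sp5"}
        groups = tp.define_branches(self._supported_tree(), smap)
        assert frozenset({"b1", "b2"}) not in {g.members for g in groups}

    def test_support_exactly_80_fails_strict_rule(self):
        tree = self._supported_tree()
        for node in tp.tree_bipartitions(tree).values():
            node.support = 80.0
        smap = {"a1": "sp1", "a2": "sp2", "b1": "sp3", "b2": "sp4", "c": "sp5"}
        assert tp.define_branches(tree, smap) == []

    def test_single_species_clade_not_reported(self):
        smap = {"a1": "sp1", "a2": "sp1", "b1": "sp3", "b2": "sp4", "c": "sp5"}
        groups = tp.define_branches(self._supported_tree(), smap)
        assert frozenset({"a1", "a2"}) not in {g.members for g in groups}

    def test_unmapped_taxon_raises(self):
        with pytest.raises(tp.MappingError):
            tp.define_branches(self._supported_tree(), {"a1": "sp1"})

    def test_matches_enumeration_oracle(self):
        rng = random.Random(31)
        for _ in range(10):
            n = rng.randint(5, 12)
            tree = random_additive_tree(n, rng)
            for node in tp.tree_bipartitions(tree).values():
                node.support = rng.choice([50.0, 75.0, 85.0, 95.0, 100.0])
            taxa = [lf.name for lf in tree.leaves()]
            smap = {t: f"sp{rng.randint(1, 3)}" for t in taxa}
            got = {g.members for g in tp.define_branches(tree, smap)}
            assert got == branch_oracle_subsets(tree, smap, 80, 2)
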
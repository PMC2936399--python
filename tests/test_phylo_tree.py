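"""Tests for neighbor-joining, midpoint rooting, and cladogram conversion."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from oracles import leaf_path_lengths
from rcmtree.family_simulator import random_tree
from rcmtree.phylo_tree import midpoint_root, neighbor_joining, to_cladogram


def _additive_case(n, seed, length_range=(0.1, 2.0)):
    tree = random_tree(n, seed, branch_length_range=length_range)
    dm = tree.tip_tip_distances()
    return tree, DistanceMatrix(dm.data, list(dm.ids))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 0.8], [0.8, 0]], ["a", "b"])
        tree = neighbor_joining(dm)
        assert sorted(t.name for t in tree.tips()) == ["a", "b"]
        assert tree.tip_tip_distances()[("a", "b")] == pytest.approx(0.8)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 5], [3, 0, 4], [5, 4, 0]], list("abc"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # b_a = (d_ab + d_ac - d_bc)/2, etc.
        assert lengths == pytest.approx({"a": 2.0, "b": 1.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        true = TreeNode.read(["((a:1,b:2):1,(c:3,d:1):0);"])
        ttd = true.tip_tip_distances()
        tree = neighbor_joining(DistanceMatrix(ttd.data, list(ttd.ids)))
        assert tree.compare_biparts(true) == 0
        rec = tree.tip_tip_distances().filter(list(ttd.ids))
        assert np.abs(rec.data - ttd.data).max() < 1e-12

    def test_additive_matrices_recover_topology_and_lengths(self):
        for seed in range(30):
            n = 4 + seed % 9  # 4..12 taxa
            true, dm = _additive_case(n, seed)
            tree = neighbor_joining(dm)
            assert tree.compare_biparts(true) == 0
            rec = tree.tip_tip_distances().filter(list(dm.ids))
            assert np.abs(rec.data - dm.data).max() < 1e-9

    def test_leaf_set_always_preserved(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0.1, 1.0, size=(7, 7))
        data = (raw + raw.T) / 2
        np.fill_diagonal(data, 0)
        ids = [f"x{i}" for i in range(7)]
        tree = neighbor_joining(DistanceMatrix(data, ids))
        assert sorted(t.name for t in tree.tips()) == sorted(ids)

    def test_agrees_with_library_nj_topology(self):
        """Independent route: scikit-bio's NJ on tie-free additive input."""
        for seed in range(10):
            true, dm = _additive_case(8, 100 + seed)
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm)
            assert ours.compare_biparts(theirs) == 0

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            neighbor_joining(DistanceMatrix([[0.0]], ["a"]))


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        dm = DistanceMatrix([[0, 4], [4, 0]], ["a", "b"])
        rooted = midpoint_root(neighbor_joining(dm))
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths == pytest.approx({"a": 2.0, "b": 2.0})

    def test_caterpillar_root_on_long_pendant(self):
        # a:1, b:1 off one node; internal edge 1; c:5 -> diameter a..c = 7
        tree = TreeNode.read(["(a:1,b:1,(c:5):1);"])
        rooted = midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths["c"] == pytest.approx(3.5)
        assert depths["a"] == pytest.approx(3.5)

    def test_matches_all_pairs_path_oracle(self):
        for seed in range(30):
            n = 4 + seed % 17  # 4..20 leaves
            tree = random_tree(n, seed, branch_length_range=(0.1, 2.0))
            rooted = midpoint_root(tree)
            paths = leaf_path_lengths(tree, clamp=True)
            diameter = max(paths.values())
            depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
            assert max(depths.values()) == pytest.approx(diameter / 2)
            assert rooted.compare_biparts(tree) == 0

    def test_negative_lengths_clamped_in_path_metric(self):
        # negative internal edge counts as zero in the diameter search
        tree = TreeNode.read(["((a:1,b:1):-0.5,(c:3,d:0.5):0);"])
        rooted = midpoint_root(tree)
        # clamped diameter a..c = 1 + 0 + 3 = 4; root 2 from c on c's edge
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths["c"] == pytest.approx(2.0)

    def test_missing_lengths_rejected(self):
        tree = TreeNode.read(["((a,b),c);"])
        with pytest.raises(ValueError, match="branch lengths"):
            midpoint_root(tree)

    def test_midpoint_on_existing_node_becomes_root(self):
        # symmetric quartet: diameter path passes through the central node
        tree = TreeNode.read(["(a:1,b:1,(c:1,d:1):0);"])
        rooted = midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert max(depths.values()) == pytest.approx(1.0)


class TestCladogram:
    def test_lengths_dropped_topology_kept(self):
        tree = TreeNode.read(["((a:1,b:2):0.5,(c:3,d:1):0.2);"])
        clad = to_cladogram(tree)
        assert all(n.length is None for n in clad.traverse())
        assert clad.compare_subsets(tree) == 0

    def test_idempotent(self):
        tree = TreeNode.read(["((a:1,b:2):0.5,c:3);"])
        once = to_cladogram(tree)
        twice = to_cladogram(once)
        assert str(once) == str(twice)
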
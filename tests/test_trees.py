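"""Distance trees: neighbor joining exactness, content dendrograms, Newick."""

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio import DistanceMatrix, TreeNode

from panforge import trees
from conftest import truth_presence_matrix


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns (tree,
    pairwise path-length matrix as DataFrame)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=x) for x in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    tree = nodes[0]
    tree.length = None
    dm = tree.tip_tip_distances(labels)
    return tree, pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        t = trees.neighbor_joining(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 6, 9, 12])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        """NJ must reproduce any additive matrix: the inferred tree's
        patristic distances equal the input to numerical precision, which
        pins both topology and branch lengths."""
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            _, d = random_additive_tree(n_taxa, rng)
            t = trees.neighbor_joining(d)
            back = t.tip_tip_distances(list(d.index))
            assert np.allclose(back.data, d.to_numpy(), atol=1e-9)

    def test_matches_skbio_nj_topology(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            _, d = random_additive_tree(7, rng)
            ours = trees.neighbor_joining(d)
            theirs = skbio.tree.nj(DistanceMatrix(d.to_numpy(),
                                                  ids=list(d.index)))
            rf = ours.compare_rfd(theirs)
            assert rf == 0.0

    def test_ultrametric_matrix_matches_upgma_topology(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            # random ultrametric distances via a random dendrogram
            n = 6
            labels = [f"u{i}" for i in range(n)]
            groups = [[x] for x in labels]
            heights = [0.0] * n
            d = pd.DataFrame(0.0, index=labels, columns=labels)
            h = 0.0
            while len(groups) > 1:
                h += float(rng.uniform(0.2, 1.0))
                i, j = sorted(rng.choice(len(groups), 2, replace=False))
                for x in groups[i]:
                    for y in groups[j]:
                        d.loc[x, y] = d.loc[y, x] = 2 * h
                groups = ([groups[k] for k in range(len(groups))
                           if k not in (i, j)] + [groups[i] + groups[j]])
            nj_tree = trees.neighbor_joining(d)
            upgma = trees.hierarchical_tree(d, linkage="average")
            assert nj_tree.compare_rfd(upgma) == 0.0

    def test_negative_branch_clamped_with_warning(self):
        d = pd.DataFrame(  # non-additive: forces a negative NJ branch
            [[0, 0.869, 0.657, 0.390],
             [0.869, 0, 0.610, 0.257],
             [0.657, 0.610, 0, 0.164],
             [0.390, 0.257, 0.164, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        with pytest.warns(UserWarning, match="clamped"):
            t = trees.neighbor_joining(d)
        for node in t.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestContentTree:
    def matrix(self):
        return pd.DataFrame(
            {"s1": [1, 1, 1, 0, 0], "s2": [1, 1, 1, 0, 0],
             "s3": [1, 0, 0, 1, 1], "s4": [0, 0, 0, 1, 1],
             "s5": [0, 1, 0, 1, 0]},
            index=[f"OG{i}" for i in range(5)])

    def test_identical_profiles_distance_zero_merged_first(self):
        d = trees.jaccard_distance_matrix(self.matrix())
        assert d.loc["s1", "s2"] == 0.0
        t = trees.content_tree(self.matrix())
        pair = t.lowest_common_ancestor(["s1", "s2"])
        assert {x.name for x in pair.tips()} == {"s1", "s2"}

    def test_disjoint_og_sets_distance_one(self):
        m = pd.DataFrame({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]},
                         index=[f"OG{i}" for i in range(4)])
        d = trees.jaccard_distance_matrix(m)
        assert d.loc["a", "b"] == 1.0

    def test_dendrogram_matches_brute_force_agglomeration(self):
        """Average-linkage merges recomputed independently from first
        principles give the same merge sequence."""
        m = self.matrix()
        d = trees.jaccard_distance_matrix(m)
        # independent oracle: track merge partitions
        active = {frozenset([s]): s for s in m.columns}
        merges = []
        dd = {(a, b): d.loc[a, b] for a in m.columns for b in m.columns}
        while len(active) > 1:
            items = sorted(active.keys(), key=lambda f: sorted(f))
            best, bd = None, np.inf
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    pairs = [dd[(x, y)] for x in items[i] for y in items[j]]
                    mean = float(np.mean(pairs))
                    if mean < bd - 1e-12:
                        bd, best = mean, (items[i], items[j])
            a, b = best
            merges.append((set(a), set(b), bd))
            del active[a], active[b]
            active[a | b] = None
        t = trees.content_tree(m)
        # check every oracle merge appears as a clade with height bd/2
        for a, b, bd in merges:
            clade = t.lowest_common_ancestor(sorted(a | b))
            assert {x.name for x in clade.tips()} == a | b

    def test_invariant_under_row_permutation(self):
        m = self.matrix()
        rng = np.random.default_rng(0)
        shuffled = m.iloc[rng.permutation(len(m))]
        assert trees.to_newick(trees.content_tree(m)) == \
            trees.to_newick(trees.content_tree(shuffled))

    def test_shared_accessory_profiles_cluster_on_panel(self, panel):
        """Strains with identical planted island profiles merge below any
        strain with a different profile."""
        m = truth_presence_matrix(panel)
        profile = {}
        for s in panel.strains:
            fams = set(m.index[m[s] > 0])
            profile[s] = tuple(
                tuple(sorted(set(isl) & fams)) == tuple(sorted(isl))
                for isl in panel.truth.island_families)
        t = trees.content_tree(m)
        same = [(a, b) for a in panel.strains for b in panel.strains
                if a < b and profile[a] == profile[b]]
        if not same:
            pytest.skip("panel has no strain pair with identical profiles")
        d = trees.jaccard_distance_matrix(m)
        for a, b in same:
            diff = [c for c in panel.strains if profile[c] != profile[a]]
            assert d.loc[a, b] < min(d.loc[a, c] for c in diff)


class TestNewick:
    def test_two_leaf_form(self):
        t = TreeNode.read(["(A:1.5,B:2.5);"])
        out = trees.to_newick(t)
        assert out == "(A:1.5,B:2.5);"

    def test_round_trip_stable(self):
        rng = np.random.default_rng(1)
        t, _ = random_additive_tree(8, rng)
        once = trees.to_newick(t)
        twice = trees.to_newick(trees.from_newick(once))
        assert once == twice

    def test_quoted_labels_with_spaces_survive(self):
        t = TreeNode.read(["('strain one':1,'strain two':2);"])
        back = trees.from_newick(trees.to_newick(t))
        assert {x.name for x in back.tips()} == {"strain one", "strain two"}
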
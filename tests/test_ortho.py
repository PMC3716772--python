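"""Ortholog engine: alignment scoring, RBH graph, Markov clustering."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from sklearn.metrics import adjusted_rand_score

from panforge import ortho
from panforge.ortho import (SimilarityEdge, build_graph, make_ogs,
                            mcl_cluster, score_pairs)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(a: str, b: str, open_=-11, ext=-1) -> float:
    """Brute-force affine-gap local alignment (independent DP oracle)."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), neg)  # gap in b
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext)
            best = max(best, M[i, j])
    return best


class TestScorePairs:
    def test_identical_proteins_identity_one(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        edges = score_pairs({"a": seq, "b": seq})
        assert len(edges) == 1
        assert edges[0].identity == 1.0

    @pytest.mark.parametrize("a,b", [
        ("HEAGAWGHEE", "PAWHEAE"),
        ("MKTAYIAKQR", "MKTAYIAKQR"),
        ("MSPILGYWKIKGLVQPTRLL", "MSPNLPYWKIKALVQPTRLL"),
        ("WWWHHH", "HHHWWW"),
    ])
    def test_alignment_score_matches_dp_oracle(self, a, b):
        aligner = ortho._make_aligner()
        assert float(aligner.score(a, b)) == pytest.approx(gotoh_local(a, b))

    def test_random_pairs_pruned_by_prefilter(self):
        """Unrelated 100-aa proteins share < 2 four-mers in >= 99% of
        draws, so the prefilter skips them."""
        rng = np.random.default_rng(42)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        pruned = 0
        n_draws = 300
        for _ in range(n_draws):
            a = "".join(rng.choice(aa, 100))
            b = "".join(rng.choice(aa, 100))
            shared = ({a[i:i + 4] for i in range(97)}
                      & {b[i:i + 4] for i in range(97)})
            pruned += len(shared) < 2
        assert pruned >= 0.99 * n_draws

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_pairs({})
        with pytest.raises(ValueError, match="empty sequence"):
            score_pairs({"a": ""})


class TestBuildGraph:
    def test_single_family_two_strains_gives_rbh_edge(self):
        edges = [SimilarityEdge("s1|g", "s2|g", 100.0, 0.9)]
        g = build_graph(edges, {"s1|g": "s1", "s2|g": "s2"})
        assert g.has_edge("s1|g", "s2|g")
        assert g["s1|g"]["s2|g"]["weight"] == 1.0

    def test_non_reciprocal_best_dropped(self):
        # A's best in strain2 is B, but B's best in strain1 is C
        edges = [
            SimilarityEdge("s1|A", "s2|B", 80.0, 0.7),
            SimilarityEdge("s1|C", "s2|B", 120.0, 0.9),
        ]
        strain_of = {"s1|A": "s1", "s1|C": "s1", "s2|B": "s2"}
        g = build_graph(edges, strain_of)
        assert not g.has_edge("s1|A", "s2|B")
        assert g.has_edge("s1|C", "s2|B")

    def test_recent_duplicate_kept_as_inparalog(self):
        edges = [
            SimilarityEdge("s1|A1", "s1|A2", 150.0, 0.95),  # within strain
            SimilarityEdge("s1|A1", "s2|A", 100.0, 0.8),
            SimilarityEdge("s1|A2", "s2|A", 100.0, 0.8),
        ]
        strain_of = {"s1|A1": "s1", "s1|A2": "s1", "s2|A": "s2"}
        g = build_graph(edges, strain_of)
        assert g.has_edge("s1|A1", "s1|A2")

    def test_weak_duplicate_below_cross_strain_best_dropped(self):
        edges = [
            SimilarityEdge("s1|A1", "s1|A2", 60.0, 0.5),
            SimilarityEdge("s1|A1", "s2|A", 100.0, 0.8),
            SimilarityEdge("s1|A2", "s2|A", 100.0, 0.8),
        ]
        strain_of = {"s1|A1": "s1", "s1|A2": "s1", "s2|A": "s2"}
        g = build_graph(edges, strain_of)
        assert not g.has_edge("s1|A1", "s1|A2")


def _mcl_oracle(weights: np.ndarray, inflation=1.5, n_iter=200):
    """Step-by-step expansion/inflation iteration, independent of the
    implementation (no pruning shortcuts, plain loops)."""
    m = weights.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m = m / m.sum(axis=0)
    for _ in range(n_iter):
        m = m @ m
        m = m ** inflation
        m[m < 1e-6] = 0.0
        s = m.sum(axis=0)
        s[s == 0] = 1.0
        m = m / s
    return m


class TestMcl:
    def barbell(self):
        import networkx as nx
        g = nx.Graph()
        for tri, names in ((1.0, "abc"), (1.0, "xyz")):
            for i in range(3):
                g.add_edge(names[i], names[(i + 1) % 3], weight=tri)
        g.add_edge("c", "x", weight=0.05)
        return g

    def test_disjoint_triangles_two_clusters(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"),
                          ("x", "y"), ("y", "z"), ("z", "x")], weight=1.0)
        part = mcl_cluster(g)
        assert sorted(map(sorted, part)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_isolated_node_singleton(self):
        import networkx as nx
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b", weight=1.0)
        part = mcl_cluster(g)
        assert {"lonely"} in part

    def test_barbell_splits_at_weak_edge_matching_oracle(self):
        g = self.barbell()
        part = mcl_cluster(g)
        assert sorted(map(sorted, part)) == [["a", "b", "c"], ["x", "y", "z"]]
        # oracle: iterate the raw recurrence and read clusters off the
        # limit matrix's nonzero pattern
        nodes = sorted(g.nodes)
        w = np.zeros((6, 6))
        for a, b, d in g.edges(data=True):
            i, j = nodes.index(a), nodes.index(b)
            w[i, j] = w[j, i] = d["weight"]
        limit = _mcl_oracle(w)
        reach = {i: frozenset(np.nonzero(limit[:, i] > 1e-6)[0])
                 for i in range(6)}
        # nodes flowing to the same attractor set belong together
        groups = {}
        for i in range(6):
            groups.setdefault(reach[i], set()).add(nodes[i])
        assert sorted(map(sorted, groups.values())) == \
            sorted(map(sorted, part))

    def test_partition_refines_connected_components(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(25, 0.12, seed=5)
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.uniform(0.1, 1.0))
        part = mcl_cluster(g)
        assert sorted(n for c in part for n in c) == sorted(g.nodes)
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = i
        for cluster in part:
            assert len({comp_of[n] for n in cluster}) == 1

    def test_deterministic(self):
        g = self.barbell()
        assert mcl_cluster(g) == mcl_cluster(g)


class TestMakeOgs:
    def test_single_copy_core_flagged(self):
        part = [{"s1|a", "s2|a", "s3|a"}]
        strain_of = {"s1|a": "s1", "s2|a": "s2", "s3|a": "s3"}
        ogs = make_ogs(part, strain_of)
        assert ogs[0].is_single_copy_core

    def test_duplicate_counted(self):
        part = [{"s1|a", "s1|a2", "s2|a"}]
        strain_of = {"s1|a": "s1", "s1|a2": "s1", "s2|a": "s2"}
        ogs = make_ogs(part, strain_of)
        assert ogs[0].strain_counts == {"s1": 2, "s2": 1}
        assert not ogs[0].is_single_copy_core

    def test_empty_partition(self):
        assert make_ogs([], {}) == []


class TestFamilyRecovery:
    def test_ogs_equal_planted_families(self, panel, panel_proteins, panel_ogs):
        """Under the default divergence bands the inferred OGs reproduce
        the planted families exactly (adjusted Rand index 1.0)."""
        proteins, _ = panel_proteins
        fam = panel.truth.family_of_gene
        og_of = {m: og.og_id for og in panel_ogs for m in og.members}
        genes = sorted(proteins)
        ari = adjusted_rand_score([fam[g] for g in genes],
                                  [og_of[g] for g in genes])
        assert ari == 1.0

    def test_every_protein_in_exactly_one_og(self, panel_proteins, panel_ogs):
        proteins, _ = panel_proteins
        seen = [m for og in panel_ogs for m in og.members]
        assert sorted(seen) == sorted(proteins)

    def test_determinism(self, panel_proteins):
        proteins, strain_of = panel_proteins
        sub = dict(sorted(proteins.items())[:60])
        sub_strain = {k: strain_of[k] for k in sub}
        a = ortho.cluster_proteins(sub, sub_strain)
        b = ortho.cluster_proteins(sub, sub_strain)
        assert [og.members for og in a] == [og.members for og in b]
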
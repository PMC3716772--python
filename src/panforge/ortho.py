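"""Ortholog-group inference.

All-vs-all protein comparison at desk scale: a shared k-mer count prefilter
prunes the quadratic pair space, surviving pairs are scored by local
alignment (BLOSUM62, affine gaps), inter-strain edges are kept when
reciprocal-best, within-strain in-paralog edges are kept when they outscore
the gene's best cross-strain hit, and the resulting weighted graph is
partitioned by Markov clustering (expansion/inflation, default inflation
1.5). One ortholog group (OG) per cluster.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter, defaultdict
from typing import Mapping

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclasses.dataclass(frozen=True)
class SimilarityEdge:
    """Scored protein pair, stored with a < b canonically."""

    a: str
    b: str
    score: float
    identity: float

    def __post_init__(self):
        if self.a >= self.b:
            raise ValueError("edges must be stored with a < b")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclasses.dataclass
class OrthologGroup:
    og_id: str
    members: list[str]
    strain_counts: dict[str, int]
    annotation: str = ""

    @property
    def n_strains(self) -> int:
        return len(self.strain_counts)

    @property
    def is_single_copy_core(self) -> bool:
        return all(c == 1 for c in self.strain_counts.values())


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _alignment_identity(alignment) -> tuple[float, int]:
    """(fraction identical over aligned columns, aligned length)."""
    ta, qa = alignment[0], alignment[1]
    n_cols = len(ta)
    if n_cols == 0:
        return 0.0, 0
    ident = sum(1 for x, y in zip(ta, qa) if x == y and x != "-")
    return ident / n_cols, n_cols


def score_pairs(
    proteins: Mapping[str, str],
    k: int = 4,
    min_shared_kmers: int = 2,
    adaptive_kmer_frac: float = 0.02,
    min_score: float = 50.0,
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> list[SimilarityEdge]:
    """All-vs-all similarity edges above the keep cutoffs.

    Pairs sharing fewer than ``max(min_shared_kmers, adaptive_kmer_frac *
    smaller k-mer count)`` k-mers are never aligned: the absolute floor
    governs short sequences, while the length-proportional term keeps the
    shared-k-mer null (which grows with the product of sequence lengths)
    from flooding long pairs through the prefilter. An aligned pair is kept
    when score >= ``min_score`` or when identity >= ``min_identity`` over an
    alignment covering >= ``min_coverage`` of the shorter sequence.
    """
    if not proteins:
        raise ValueError("empty protein set")
    for name, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence: {name}")
    names = sorted(proteins)
    kmer_sets = {n: _kmers(proteins[n], k) for n in names}
    bucket: dict[str, list[str]] = defaultdict(list)
    for n in names:
        for km in kmer_sets[n]:
            bucket[km].append(n)
    shared: Counter[tuple[str, str]] = Counter()
    for members in bucket.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared[(members[i], members[j])] += 1

    aligner = _make_aligner()
    edges = []
    for (a, b), n_shared in sorted(shared.items()):
        thr = max(min_shared_kmers,
                  int(adaptive_kmer_frac * min(len(kmer_sets[a]), len(kmer_sets[b]))))
        if n_shared < thr:
            continue
        short = min(len(proteins[a]), len(proteins[b]))
        # score-only pass first; the traceback is ~5x more expensive. A pair
        # that can satisfy the identity/coverage route but not min_score must
        # be short (identity >= 0.4 over >= half the shorter sequence scores
        # far above 50 once the sequences pass ~60 residues).
        score = float(aligner.score(proteins[a], proteins[b]))
        if score <= 0:
            continue
        if score < min_score and short >= 60:
            continue
        alns = aligner.align(proteins[a], proteins[b])
        identity, n_cols = _alignment_identity(alns[0])
        keep = score >= min_score or (
            identity >= min_identity and n_cols >= min_coverage * short)
        if keep:
            edges.append(SimilarityEdge(a=a, b=b, score=score, identity=identity))
    return edges


def build_graph(
    edges: list[SimilarityEdge],
    strain_of: Mapping[str, str],
) -> nx.Graph:
    """RBH + in-paralog graph with weights normalized to [0, 1].

    An inter-strain edge survives iff each endpoint is among the other's
    best-scoring hits in that strain (ties kept). A within-strain edge
    survives iff its score is >= the gene's best inter-strain score (genes
    with no inter-strain hit keep all their within-strain edges). Weights
    are scores divided by the maximum retained score.
    """
    # best inter-strain score per (gene, other strain), and overall
    best_per_strain: dict[tuple[str, str], float] = {}
    best_inter: dict[str, float] = {}
    for e in edges:
        sa, sb = strain_of[e.a], strain_of[e.b]
        if sa == sb:
            continue
        for g, other in ((e.a, sb), (e.b, sa)):
            key = (g, other)
            if e.score > best_per_strain.get(key, -1.0):
                best_per_strain[key] = e.score
            if e.score > best_inter.get(g, -1.0):
                best_inter[g] = e.score

    g = nx.Graph()
    g.add_nodes_from(strain_of)
    kept: list[SimilarityEdge] = []
    for e in edges:
        sa, sb = strain_of[e.a], strain_of[e.b]
        if sa != sb:
            if (e.score >= best_per_strain[(e.a, sb)]
                    and e.score >= best_per_strain[(e.b, sa)]):
                kept.append(e)
        else:
            thr_a = best_inter.get(e.a)
            thr_b = best_inter.get(e.b)
            ok_a = thr_a is None or e.score >= thr_a
            ok_b = thr_b is None or e.score >= thr_b
            if ok_a and ok_b:
                kept.append(e)
    if kept:
        max_score = max(e.score for e in kept)
        for e in kept:
            g.add_edge(e.a, e.b, weight=e.score / max_score, score=e.score)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    prune_below: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[set[str]]:
    """Markov clustering of a weighted graph; returns a node partition.

    Each connected component is clustered independently (expansion cannot
    cross components, so this is exact and keeps the matrices small).
    Within a component: add unit self-loops, column-normalize, then repeat
    expansion (matrix square) and inflation (entrywise power, renormalize)
    with pruning of entries < ``prune_below`` until the largest entry change
    is < ``tol``. Clusters are the connected components of the limit
    matrix's nonzero pattern.
    """
    clusters: list[set[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(set(nodes))
            continue
        idx = {n: i for i, n in enumerate(nodes)}
        m = np.zeros((len(nodes), len(nodes)))
        for a, b, data in graph.subgraph(comp).edges(data=True):
            w = float(data.get("weight", 1.0))
            m[idx[a], idx[b]] = w
            m[idx[b], idx[a]] = w
        np.fill_diagonal(m, 1.0)
        m /= m.sum(axis=0, keepdims=True)
        converged = False
        for _ in range(max_iter):
            prev = m
            m = m @ m
            m = np.power(m, inflation)
            m[m < prune_below] = 0.0
            colsum = m.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            m = m / colsum
            if np.max(np.abs(m - prev)) < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"MCL did not converge in {max_iter} iterations on a "
                f"{len(nodes)}-node component; using partial result")
        support = nx.Graph()
        support.add_nodes_from(range(len(nodes)))
        rows, cols = np.nonzero(m > prune_below)
        support.add_edges_from(zip(rows.tolist(), cols.tolist()))
        for sub in nx.connected_components(support):
            clusters.append({nodes[i] for i in sub})
    return clusters


def make_ogs(
    partition: list[set[str]],
    strain_of: Mapping[str, str],
    annotation_of: Mapping[str, str] | None = None,
) -> list[OrthologGroup]:
    """One OG per cluster, with per-strain copy counts and a consensus
    annotation (most frequent member annotation; ties broken
    alphabetically). Stable ids follow sorted member order."""
    keyed = sorted(partition, key=lambda c: sorted(c))
    ogs = []
    for i, cluster in enumerate(keyed):
        members = sorted(cluster)
        counts: dict[str, int] = {}
        for m in members:
            counts[strain_of[m]] = counts.get(strain_of[m], 0) + 1
        annotation = ""
        if annotation_of:
            anns = Counter(annotation_of.get(m, "") for m in members)
            annotation = sorted(anns.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        ogs.append(OrthologGroup(
            og_id=f"OG{i:05d}", members=members,
            strain_counts=dict(sorted(counts.items())),
            annotation=annotation))
    return ogs


def cluster_proteins(
    proteins: Mapping[str, str],
    strain_of: Mapping[str, str],
    annotation_of: Mapping[str, str] | None = None,
    inflation: float = 1.5,
    **score_kwargs,
) -> list[OrthologGroup]:
    """score_pairs -> build_graph -> mcl_cluster -> make_ogs."""
    edges = score_pairs(proteins, **score_kwargs)
    graph = build_graph(edges, strain_of)
    partition = mcl_cluster(graph, inflation=inflation)
    return make_ogs(partition, strain_of, annotation_of)
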
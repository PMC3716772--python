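"""Two strain trees from one panel.

The sequence tree summarises evolutionary relatedness: pairwise distances
are 1 - fractional identity from global alignment of each single-copy core
OG, combined as a length-weighted mean over OGs, and agglomerated by
canonical neighbor joining (a distance-based substitute for a concatenated-
alignment maximum-likelihood tree, adequate at the divergences the panel
spans). The content tree summarises genome content: Jaccard distances
between strains' OG presence vectors, clustered hierarchically (average
linkage by default). Comparing the two separates vertical descent from
gene gain and loss.

Trees are held as :class:`skbio.TreeNode`; Newick serialisation and
parsing round-trip through scikit-bio.
"""

from __future__ import annotations

import io as _stdio
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def pairwise_identity_distance(a: str, b: str, aligner=None) -> tuple[float, int]:
    """(1 - fractional identity, alignment length) from global alignment."""
    aligner = aligner or _global_aligner()
    aln = aligner.align(a, b)[0]
    ta, qa = aln[0], aln[1]
    ident = sum(1 for x, y in zip(ta, qa) if x == y and x != "-")
    return 1.0 - ident / len(ta), len(ta)


def core_distance(
    core_og_members: Mapping[str, Mapping[str, str]],
    strains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Length-weighted mean per-OG alignment distance between strains.

    ``core_og_members`` maps og_id -> {strain: protein}; every OG must have
    exactly one member per strain (single-copy core).
    """
    if not core_og_members:
        raise ValueError("need at least one single-copy core OG")
    first = next(iter(core_og_members.values()))
    strains = sorted(strains) if strains is not None else sorted(first)
    if len(strains) < 3:
        raise ValueError("need at least 3 strains")
    aligner = _global_aligner()
    n = len(strains)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for og_id in sorted(core_og_members):
        members = core_og_members[og_id]
        for i in range(n):
            for j in range(i + 1, n):
                d, length = pairwise_identity_distance(
                    members[strains[i]], members[strains[j]], aligner)
                num[i, j] += d * length
                den[i, j] += length
    with np.errstate(invalid="ignore"):
        dist = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    dist = dist + dist.T
    return pd.DataFrame(dist, index=strains, columns=strains)


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Canonical neighbor joining (Q-criterion) on a symmetric distance
    matrix; returns an unrooted tree (trifurcating root). Negative branch
    lengths are clamped to zero with a warning. Ties in the Q matrix break
    toward the lexicographically smallest label pair, for determinism."""
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    dm = d.to_numpy(dtype=float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(x)) for x in labels]
    names: list[str] = [str(x) for x in labels]

    def _set_len(node: TreeNode, length: float) -> None:
        if length < -1e-12:
            warnings.warn(f"negative branch length {length:.3g} clamped to 0")
        node.length = max(0.0, float(length))

    while len(nodes) > 3:
        n = len(nodes)
        r = dm.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dm[i, j] - r[i] - r[j]
                key = tuple(sorted((names[i], names[j])))
                if q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12
                        and best is not None
                        and key < tuple(sorted((names[best[0]], names[best[1]])))):
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = dm[i, j] - li
        parent = TreeNode()
        _set_len(nodes[i], li)
        _set_len(nodes[j], lj)
        parent.extend([nodes[i], nodes[j]])
        new_d = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        dm2 = np.zeros((len(keep) + 1, len(keep) + 1))
        dm2[:-1, :-1] = dm[np.ix_(keep, keep)]
        dm2[-1, :-1] = new_d[keep]
        dm2[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        dm = dm2

    # final trifurcation
    root = TreeNode()
    l0 = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    l1 = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    l2 = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    for node, length in zip(nodes, (l0, l1, l2)):
        _set_len(node, length)
    root.extend(nodes)
    return root


def jaccard_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distance (1 - |A∩B|/|A∪B|) between strain presence
    vectors (columns of the OG x strain matrix)."""
    strains = list(matrix.columns)
    x = matrix.to_numpy(dtype=bool)
    n = len(strains)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum(x[:, i] & x[:, j])
            union = np.sum(x[:, i] | x[:, j])
            out[i, j] = out[j, i] = 1.0 - (inter / union if union else 1.0)
    return pd.DataFrame(out, index=strains, columns=strains)


def hierarchical_tree(
    d: pd.DataFrame, linkage: str = "average"
) -> TreeNode:
    """Agglomerative clustering of a distance matrix into a rooted
    dendrogram (ultrametric branch lengths from merge heights). Linkage is
    average, complete or single; ties merge the lexicographically smallest
    cluster pair."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    labels = [str(x) for x in d.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 strains")
    dm = d.to_numpy(dtype=float).copy()
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    nodes: list[TreeNode] = [TreeNode(name=x) for x in labels]
    heights: list[float] = [0.0] * len(labels)
    keys: list[str] = list(labels)

    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = _linkage_distance(dm, clusters[i], clusters[j], linkage)
                key = tuple(sorted((keys[i], keys[j])))
                if dij < best_d - 1e-12 or (
                        abs(dij - best_d) <= 1e-12 and best is not None
                        and key < tuple(sorted((keys[best[0]], keys[best[1]])))):
                    best_d = dij
                    best = (i, j)
        i, j = best
        h = best_d / 2.0
        parent = TreeNode()
        for idx in (i, j):
            child = nodes[idx]
            child.length = max(0.0, h - heights[idx])
            parent.append(child)
        merged = sorted(clusters[i] + clusters[j])
        keep = [k for k in range(len(clusters)) if k not in (i, j)]
        clusters = [clusters[k] for k in keep] + [merged]
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    root = nodes[0]
    root.length = None
    return root


def _linkage_distance(dm, ca, cb, linkage: str) -> float:
    block = dm[np.ix_(ca, cb)]
    if linkage == "average":
        return float(block.mean())
    if linkage == "complete":
        return float(block.max())
    return float(block.min())


def content_tree(matrix: pd.DataFrame, linkage: str = "average") -> TreeNode:
    """Genome-content dendrogram: Jaccard distances + hierarchical
    clustering of the presence/absence matrix columns."""
    return hierarchical_tree(jaccard_distance_matrix(matrix), linkage=linkage)


def to_newick(tree: TreeNode) -> str:
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(_stdio.StringIO(text), format="newick")
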
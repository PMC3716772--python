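"""Reference-anchored pseudo-assembly and GC profiling.

Draft-genome contigs are ordered by projecting their genes onto a finished
circular reference chromosome: each query gene is matched to its
reciprocal-best reference gene, each contig receives the mean of its
anchors' reference midpoints, and contigs are sorted by that mean. Anchors
of a contig that straddle the replication origin are unwrapped (reference
length added to the smaller coordinates) before averaging, so origin-
spanning contigs are placed sensibly. Contigs without anchors go to an
unplaced bin in input order. The reference gene order also assigns every
anchored OG a rank — the left-to-right ordering used to draw genome-content
bar plots and to detect variable regions.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from panforge import ortho
from panforge.models import GeneModel


@dataclasses.dataclass
class ContigAnchor:
    contig: str
    anchors: list[tuple[str, str, float]]  # (query gene, ref gene, ref midpoint)
    mean_coord: float | None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclasses.dataclass
class PseudoAssembly:
    strain: str
    ordered_contigs: list[str]
    unplaced: list[str]
    contig_anchors: dict[str, ContigAnchor]
    ref_rank_of_gene: dict[str, int]  # reference gene id -> rank

    @property
    def all_contigs(self) -> list[str]:
        return self.ordered_contigs + self.unplaced

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, cid in enumerate(self.ordered_contigs):
            a = self.contig_anchors[cid]
            rows.append((self.strain, rank, cid, a.mean_coord, a.n_anchors))
        for cid in self.unplaced:
            rows.append((self.strain, None, cid, None, 0))
        return pd.DataFrame(
            rows, columns=["strain", "rank", "contig", "mean_coord", "n_anchors"])


def match_to_reference(
    query_proteins: Mapping[str, str],
    ref_proteins: Mapping[str, str],
    **score_kwargs,
) -> dict[str, str]:
    """Reciprocal-best match of query genes onto reference genes.

    Runs the ortholog engine on the two-"strain" union (query vs reference)
    and reads query->reference pairs off the RBH edges.
    """
    proteins = dict(query_proteins) | dict(ref_proteins)
    strain_of = {g: "query" for g in query_proteins}
    strain_of |= {g: "ref" for g in ref_proteins}
    edges = ortho.score_pairs(proteins, **score_kwargs)
    graph = ortho.build_graph(edges, strain_of)
    best: dict[str, tuple[float, str]] = {}
    for a, b, data in graph.edges(data=True):
        if strain_of[a] == strain_of[b]:
            continue
        q, r = (a, b) if strain_of[a] == "query" else (b, a)
        sc = float(data["score"])
        if q not in best or sc > best[q][0] or (sc == best[q][0] and r < best[q][1]):
            best[q] = (sc, r)
    return {q: r for q, (_, r) in best.items()}


def anchor_and_order(
    strain: str,
    genes: Sequence[GeneModel],
    ref_genes: Sequence[GeneModel],
    ref_length: int,
    gene_to_ref: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    contig_input_order: Sequence[str] | None = None,
    **score_kwargs,
) -> PseudoAssembly:
    """Order one strain's contigs along the reference chromosome.

    ``gene_to_ref`` (query gene id -> reference gene id) may be precomputed;
    otherwise it is derived here via :func:`match_to_reference`.
    """
    if not ref_genes:
        raise ValueError("reference without annotation")
    ref_by_id = {g.gene_id: g for g in ref_genes}
    if gene_to_ref is None:
        gene_to_ref = match_to_reference(
            {g.gene_id: g.protein for g in genes},
            {g.gene_id: g.protein for g in ref_genes},
            **score_kwargs)

    ref_order = sorted(ref_genes, key=lambda g: g.start)
    rank_of_ref = {g.gene_id: i for i, g in enumerate(ref_order)}

    per_contig: dict[str, list[tuple[str, str, float]]] = {}
    contigs_seen: list[str] = []
    for g in genes:
        if g.contig not in per_contig:
            per_contig[g.contig] = []
            contigs_seen.append(g.contig)
        r = gene_to_ref.get(g.gene_id)
        if r is not None and r in ref_by_id:
            rg = ref_by_id[r]
            per_contig[g.contig].append((g.gene_id, r, (rg.start + rg.end) / 2.0))
    if contig_input_order is not None:
        for cid in contig_input_order:
            if cid not in per_contig:
                per_contig[cid] = []
                contigs_seen.append(cid)

    anchors: dict[str, ContigAnchor] = {}
    for cid in contigs_seen:
        pts = per_contig[cid]
        if not pts:
            anchors[cid] = ContigAnchor(cid, [], None)
            continue
        coords = [m for _, _, m in pts]
        # unwrap across the circular origin: when the anchor spread exceeds
        # half the reference, try shifting the small coordinates up one
        # turn and keep whichever representation has the smaller spread
        # (a long contig can legitimately span half the chromosome)
        if max(coords) - min(coords) > ref_length / 2:
            shifted = [c + ref_length if c < ref_length / 2 else c
                       for c in coords]
            if max(shifted) - min(shifted) < max(coords) - min(coords):
                coords = shifted
        mean = sum(coords) / len(coords)
        anchors[cid] = ContigAnchor(cid, pts, mean)

    placed = [cid for cid in contigs_seen if anchors[cid].mean_coord is not None]
    if contig_lengths is None:
        contig_lengths = {}

    def _key(cid: str):
        return (anchors[cid].mean_coord, -contig_lengths.get(cid, 0), cid)

    placed.sort(key=_key)
    unplaced = [cid for cid in contigs_seen if anchors[cid].mean_coord is None]
    return PseudoAssembly(
        strain=strain, ordered_contigs=placed, unplaced=unplaced,
        contig_anchors=anchors, ref_rank_of_gene=rank_of_ref)


def og_ranks(
    ogs: Sequence[ortho.OrthologGroup],
    ref_gene_ranks: Mapping[str, int],
    gene_to_ref: Mapping[str, str],
) -> dict[str, int]:
    """Project reference gene order onto OGs.

    An OG's rank is the smallest reference rank among its members' matched
    reference genes; OGs with no reference match get no rank (they end up in
    the unplaced bin of presence/absence plots).
    """
    out: dict[str, int] = {}
    for og in ogs:
        ranks = [ref_gene_ranks[gene_to_ref[m]]
                 for m in og.members
                 if m in gene_to_ref and gene_to_ref[m] in ref_gene_ranks]
        if ranks:
            out[og.og_id] = min(ranks)
    return out


def gc_profile(
    sequences: Sequence[tuple[str, str]],
    window: int = 5000,
    step: int = 1000,
) -> pd.DataFrame:
    """Sliding-window G+C fraction over contigs in pseudo-assembly order.

    Ambiguous bases are excluded from numerator and denominator. Returns a
    frame with contig, window start/end (contig coordinates) and gc.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    rows = []
    for cid, seq in sequences:
        s = seq.upper()
        n = len(s)
        starts = range(0, max(1, n - window + 1), step) if n >= window else [0]
        for w0 in starts:
            chunk = s[w0:w0 + window]
            gc = chunk.count("G") + chunk.count("C")
            at = chunk.count("A") + chunk.count("T")
            denom = gc + at
            rows.append((cid, w0, min(n, w0 + window),
                         gc / denom if denom else float("nan")))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gc"])
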
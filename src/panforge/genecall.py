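"""Consensus ORF calling from multiple predictor tracks.

Predictors of bacterial genes agree well on the stop codon of a gene and
disagree mostly on the start, so the identity notion for the vote is
(contig, strand, stop coordinate): predictions sharing those three form one
candidate, whose interval is taken from the longest supporter. A candidate
is accepted when a strict majority of predictors support it (> n/2; both
the identity notion and the threshold are configurable). Finally, genes on
the same contig may overlap by at most 100 bp; while any pair exceeds that,
the shorter member of the worst pair is discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from panforge import io as pio
from panforge.models import GeneModel


@dataclasses.dataclass(frozen=True)
class PredictedOrf:
    """A single predictor's call, 0-based half-open coordinates."""

    strain: str
    contig: str
    start: int
    end: int
    strand: str
    predictor: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def stop_coord(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclasses.dataclass
class Candidate:
    """ORFs sharing (contig, strand, stop); interval = longest member's."""

    contig: str
    strand: str
    stop: int
    start: int
    end: int
    supporters: frozenset[str]  # predictor ids

    @property
    def support(self) -> int:
        return len(self.supporters)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ConsensusGeneSet:
    strain: str
    genes: list[GeneModel]
    support_of: dict[str, frozenset[str]]  # gene_id -> predictors
    discard_log: list[tuple[str, str]]  # (description, reason)


def orfs_from_tracks(
    strain: str, tracks: dict[str, list[pio.GffFeature]]
) -> list[PredictedOrf]:
    """Flatten per-predictor GFF3 features into PredictedOrf records."""
    out = []
    for pred, feats in sorted(tracks.items()):
        for f in feats:
            out.append(PredictedOrf(
                strain=strain, contig=f.contig, start=f.start, end=f.end,
                strand=f.strand, predictor=pred))
    return out


def group_by_stop(orfs: Sequence[PredictedOrf]) -> list[Candidate]:
    """Group ORFs of one strain into stop-anchored candidates."""
    strains = {o.strain for o in orfs}
    if len(strains) > 1:
        raise ValueError(f"mixed-strain input: {sorted(strains)}")
    groups: dict[tuple[str, str, int], list[PredictedOrf]] = {}
    for o in orfs:
        groups.setdefault((o.contig, o.strand, o.stop_coord), []).append(o)
    out = []
    for (contig, strand, stop), members in sorted(groups.items()):
        longest = max(members, key=lambda o: o.end - o.start)
        out.append(Candidate(
            contig=contig, strand=strand, stop=stop,
            start=longest.start, end=longest.end,
            supporters=frozenset(m.predictor for m in members)))
    return out


def majority_vote(
    candidates: Iterable[Candidate],
    n_predictors: int,
    min_support_fraction: float = 0.5,
) -> list[Candidate]:
    """Keep candidates with support strictly above
    ``min_support_fraction * n_predictors`` (default: strict majority)."""
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    accepted = []
    for c in candidates:
        if c.support > n_predictors:
            raise ValueError(
                f"candidate at {c.contig}:{c.start}-{c.end} supported by "
                f"{c.support} predictors but only {n_predictors} declared")
        if c.support > min_support_fraction * n_predictors:
            accepted.append(c)
    return accepted


def _overlap(a: Candidate, b: Candidate) -> int:
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def resolve_overlaps(
    strain: str,
    accepted: Sequence[Candidate],
    max_overlap: int = 100,
) -> ConsensusGeneSet:
    """Discard the shorter member of every pair overlapping > ``max_overlap``.

    Pairs are processed in descending overlap size; equal lengths discard
    the later-starting ORF. Overlap is measured on nucleotide intervals
    irrespective of strand; exactly ``max_overlap`` bp is allowed.
    """
    alive = list(accepted)
    log: list[tuple[str, str]] = []
    while True:
        worst = None
        worst_ov = max_overlap
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                ov = _overlap(alive[i], alive[j])
                if ov > worst_ov:
                    worst_ov = ov
                    worst = (i, j)
        if worst is None:
            break
        a, b = alive[worst[0]], alive[worst[1]]
        if a.length != b.length:
            loser = a if a.length < b.length else b
        else:
            loser = a if a.start > b.start else b
        alive.remove(loser)
        log.append((
            f"{loser.contig}:{loser.start}-{loser.end}({loser.strand})",
            f"overlap {worst_ov} bp > {max_overlap} with longer ORF",
        ))
    genes = []
    support = {}
    for c in sorted(alive, key=lambda c: (c.contig, c.start, c.end, c.strand)):
        gid = f"{strain}|{c.contig}:{c.start}-{c.end}({c.strand})"
        genes.append(GeneModel(
            gene_id=gid, strain=strain, contig=c.contig,
            start=c.start, end=c.end, strand=c.strand))
        support[gid] = c.supporters
    return ConsensusGeneSet(strain=strain, genes=genes,
                            support_of=support, discard_log=log)


def call_genes(
    strain: str,
    tracks: dict[str, list[pio.GffFeature]],
    contigs: dict[str, str] | None = None,
    min_support_fraction: float = 0.5,
    max_overlap: int = 100,
) -> ConsensusGeneSet:
    """Full consensus calling for one strain; fills in protein sequences
    (translation table 11) when contig sequences are given."""
    orfs = orfs_from_tracks(strain, tracks)
    cands = group_by_stop(orfs)
    accepted = majority_vote(cands, len(tracks), min_support_fraction)
    consensus = resolve_overlaps(strain, accepted, max_overlap)
    if contigs is not None:
        translated = []
        for g in consensus.genes:
            cds = contigs[g.contig][g.start:g.end]
            if g.strand == "-":
                cds = pio.reverse_complement(cds)
            translated.append(dataclasses.replace(
                g, protein=pio.translate_cds(cds)))
        consensus.genes = translated
        consensus.support_of = {
            g.gene_id: consensus.support_of[g.gene_id] for g in translated}
    return consensus
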
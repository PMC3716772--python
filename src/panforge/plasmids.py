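"""Plasmid-contig classification.

A contig is scored against four lines of evidence: (1) its genes do not map
to the reference chromosome, (2) it encodes typical plasmid functions
(replication initiator, mob/tra, relaxase, partitioning, toxin-antitoxin),
(3) it matches a known plasmid sequence over most of its length, (4) it
appears circular — an exact terminal repeat left by assembling a circular
molecule. One satisfied criterion yields a putative plasmid call, two or
more a confident one. OGs whose members all lie on plasmid-called contigs
form the "plasmid pan-genome".
"""

from __future__ import annotations

import dataclasses
import re
from typing import Mapping, Sequence

import edlib

from panforge.models import GeneModel
from panforge.ortho import OrthologGroup

#: annotation terms counted as typical plasmid functions
PLASMID_KEYWORDS = [
    r"replication initiator", r"\brep[AB]?\b", r"\bmob[A-Z]?\b",
    r"\btra[A-Z]\b", r"relaxase", r"\bpar[AB]\b", r"partitioning",
    r"toxin-antitoxin", r"antitoxin", r"plasmid",
]
_KEYWORD_RE = re.compile("|".join(PLASMID_KEYWORDS), re.IGNORECASE)


@dataclasses.dataclass
class PlasmidEvidence:
    contig: str
    c1_chrom_map_fraction: float | None  # None when the contig has no genes
    c2_keyword_hits: list[str]
    c3_known_plasmid_identity: float
    c4_circular: bool
    c4_overlap: int
    call: str = ""  # chromosomal | putative_plasmid | plasmid
    chrom_map_cutoff: float = 0.2

    @property
    def criteria(self) -> tuple[bool, bool, bool, bool]:
        c1 = (self.c1_chrom_map_fraction is not None
              and self.c1_chrom_map_fraction < self.chrom_map_cutoff)
        return (c1, bool(self.c2_keyword_hits),
                self.c3_known_plasmid_identity > 0, self.c4_circular)

    @property
    def n_criteria(self) -> int:
        return sum(self.criteria)


def detect_circularity(
    sequence: str, min_overlap: int = 50, max_mismatch: int = 0
) -> tuple[bool, int]:
    """Exact terminal-repeat detection: circular iff a prefix of length >=
    ``min_overlap`` equals the suffix of the same length; the longest such
    overlap is reported. ``max_mismatch`` > 0 is not supported (assembler
    overlaps are exact copies)."""
    if max_mismatch != 0:
        raise NotImplementedError("only exact terminal repeats are detected")
    n = len(sequence)
    if n <= 2 * min_overlap:
        raise ValueError("sequence shorter than twice min_overlap")
    # an overlap of length k means the prefix seed of min_overlap bp
    # reappears at position n - k; scan the tail for that seed (C-speed
    # find) and verify each candidate, longest first
    seed = sequence[:min_overlap]
    best = 0
    i = sequence.find(seed, n - n // 2)
    while i != -1:
        k = n - i
        if k >= min_overlap and sequence[:k] == sequence[i:]:
            best = k
            break
        i = sequence.find(seed, i + 1)
    return best >= min_overlap, best


def _known_plasmid_match(
    sequence: str,
    known_plasmids: Mapping[str, str],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    window: int = 1000,
) -> float:
    """Identity of the contig against the known-plasmid set.

    The contig is cut into windows; each window is located inside a known
    plasmid by semi-global alignment (edlib HW mode: free gaps at the
    reference ends). When windows totalling >= ``min_coverage`` of the
    contig match at >= ``min_identity``, the length-weighted mean identity
    of those windows is returned; otherwise 0.0. A shared 16-mer prescreen
    skips references with no exact seed in common.
    """
    best = 0.0
    for ref in known_plasmids.values():
        ref_kmers = {ref[i:i + 16] for i in range(0, len(ref) - 15)}
        seeds = (sequence[i:i + 16] for i in range(0, len(sequence) - 15, 64))
        if not any(s in ref_kmers for s in seeds):
            continue
        covered = 0
        total = 0
        weighted = 0.0
        for w0 in range(0, len(sequence), window):
            chunk = sequence[w0:w0 + window]
            if len(chunk) < 50:
                continue
            res = edlib.align(chunk, ref, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(chunk)
            total += len(chunk)
            if ident >= min_identity:
                covered += len(chunk)
                weighted += ident * len(chunk)
        if total and covered / total >= min_coverage:
            best = max(best, weighted / covered)
    return best


def evaluate_criteria(
    contig: str,
    sequence: str,
    genes: Sequence[GeneModel],
    reference_mapped: set[str],
    known_plasmids: Mapping[str, str],
    chrom_map_cutoff: float = 0.2,
    min_overlap: int = 50,
) -> PlasmidEvidence:
    """Score the four plasmid criteria for one contig.

    ``reference_mapped`` is the set of gene ids (of this strain) that have a
    reference-chromosome ortholog. A contig with no genes yields no
    chromosome-mapping evidence (criterion 1 stays unsatisfied).
    """
    genes = [g for g in genes if g.contig == contig]
    if genes:
        mapped = sum(1 for g in genes if g.gene_id in reference_mapped)
        c1_frac: float | None = mapped / len(genes)
    else:
        c1_frac = None
    hits = sorted({g.annotation for g in genes
                   if g.annotation and _KEYWORD_RE.search(g.annotation)})
    ident = _known_plasmid_match(sequence, known_plasmids)
    if len(sequence) > 2 * min_overlap:
        circ, ov = detect_circularity(sequence, min_overlap=min_overlap)
    else:
        circ, ov = False, 0
    ev = PlasmidEvidence(
        contig=contig, c1_chrom_map_fraction=c1_frac, c2_keyword_hits=hits,
        c3_known_plasmid_identity=ident, c4_circular=circ, c4_overlap=ov,
        chrom_map_cutoff=chrom_map_cutoff)
    ev.call = _call(ev.n_criteria)
    return ev


def _call(n_criteria: int) -> str:
    if n_criteria >= 2:
        return "plasmid"
    if n_criteria == 1:
        return "putative_plasmid"
    return "chromosomal"


def classify(
    evidence: Sequence[PlasmidEvidence],
    ogs: Sequence[OrthologGroup] | None = None,
    contig_of_gene: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Final per-contig calls plus the plasmid pan-genome OG subset.

    The plasmid pan-genome contains OGs whose members all lie on contigs
    called ``plasmid`` (confident tier).
    """
    calls = {ev.contig: _call(ev.n_criteria) for ev in evidence}
    plasmid_ogs: list[str] = []
    if ogs is not None and contig_of_gene is not None:
        plasmid_contigs = {c for c, call in calls.items() if call == "plasmid"}
        for og in ogs:
            locs = {contig_of_gene.get(m) for m in og.members}
            if locs and locs <= plasmid_contigs:
                plasmid_ogs.append(og.og_id)
    return calls, sorted(plasmid_ogs)


def evidence_frame(evidence: Sequence[PlasmidEvidence]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for ev in evidence:
        c1, c2, c3, c4 = ev.criteria
        rows.append((
            ev.contig, ev.c1_chrom_map_fraction, int(c1),
            "|".join(ev.c2_keyword_hits), int(c2),
            round(ev.c3_known_plasmid_identity, 4), int(c3),
            int(c4), ev.c4_overlap, ev.call))
    return pd.DataFrame(rows, columns=[
        "contig", "chrom_map_fraction", "c1", "keyword_hits", "c2",
        "known_plasmid_identity", "c3", "c4_circular", "c4_overlap", "call"])
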
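"""CRISPR array detection, spacer cataloguing and strain typing.

An array is a run of near-identical direct repeats (here expected around
36 nt) separated by unique spacers. Detection nucleates on exact 12-mers
recurring at regular offsets (one period = repeat + spacer), extends the
repeat outward to maximal agreement against the consensus, and reports
arrays with at least three repeats. Spacers are the inter-repeat segments;
across strains they are catalogued reverse-complement-aware, and strains
are typed by their exact ordered spacer content (strains with no array get
type 0) — spacer number and identity both distinguish types.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Mapping, Sequence

import pandas as pd

from panforge.io import reverse_complement

_SEED_K = 12


@dataclasses.dataclass
class CrisprArray:
    strain: str
    contig: str
    start: int
    end: int
    repeat: str  # consensus
    spacers: list[str]
    n_repeats: int
    truncated: bool = False  # abuts a contig end (draft-assembly caveat)

    def __post_init__(self):
        if self.n_repeats < 3:
            raise ValueError("array needs >= 3 repeats")
        if len(self.spacers) != self.n_repeats - 1:
            raise ValueError("spacer count must be n_repeats - 1")


def _consensus(strings: list[str]) -> str:
    out = []
    for col in zip(*strings):
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(out)


def find_arrays(
    strain: str,
    contig: str,
    sequence: str,
    repeat_len_range: tuple[int, int] = (23, 47),
    spacer_len_range: tuple[int, int] = (20, 50),
    min_repeats: int = 3,
    max_repeat_mismatch: int = 1,
) -> list[CrisprArray]:
    """Detect CRISPR arrays on one contig.

    Candidate anchors are exact 12-mers whose successive occurrences are one
    plausible period apart (repeat + spacer length bands). Each candidate is
    extended to the maximal repeat window where every occurrence agrees with
    the column consensus up to ``max_repeat_mismatch`` total mismatches per
    repeat copy. Overlapping candidates resolve to the highest repeat count
    (ties: leftmost).
    """
    n = len(sequence)
    min_period = repeat_len_range[0] + spacer_len_range[0]
    max_period = repeat_len_range[1] + spacer_len_range[1]
    if n < 3 * repeat_len_range[0]:
        return []

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - _SEED_K + 1):
        positions[sequence[i:i + _SEED_K]].append(i)

    candidates: list[CrisprArray] = []
    seen_anchor_sets: set[tuple[int, ...]] = set()
    for kmer, pos in positions.items():
        if len(pos) < min_repeats:
            continue
        # maximal chains of occurrences with plausible periods
        chains: list[list[int]] = []
        chain = [pos[0]]
        for p in pos[1:]:
            gap = p - chain[-1]
            if min_period <= gap <= max_period:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for anchors in chains:
            if len(anchors) < min_repeats:
                continue
            key = tuple(anchors)
            if key in seen_anchor_sets:
                continue
            seen_anchor_sets.add(key)
            arr = _extend_candidate(
                strain, contig, sequence, anchors,
                repeat_len_range, spacer_len_range, max_repeat_mismatch)
            if arr is not None:
                candidates.append(arr)

    # resolve overlaps: most repeats wins, then leftmost
    candidates.sort(key=lambda a: (-a.n_repeats, a.start, a.end))
    chosen: list[CrisprArray] = []
    for c in candidates:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda a: a.start)
    return chosen


def _extend_candidate(
    strain: str,
    contig: str,
    sequence: str,
    anchors: list[int],
    repeat_len_range: tuple[int, int],
    spacer_len_range: tuple[int, int],
    max_repeat_mismatch: int,
) -> CrisprArray | None:
    n = len(sequence)
    gaps = [b - a for a, b in zip(anchors, anchors[1:])]
    max_repeat = min(min(gaps), repeat_len_range[1])

    def _column_ok(off: int) -> bool:
        chars = [sequence[a + off] for a in anchors
                 if 0 <= a + off < n]
        if len(chars) != len(anchors):
            return False
        return Counter(chars).most_common(1)[0][1] >= len(chars) - max(
            0, max_repeat_mismatch)

    left = 0
    while left < max_repeat and _column_ok(-(left + 1)):
        left += 1
    right = _SEED_K
    while (left + right) < max_repeat and _column_ok(right):
        right += 1
    rep_len = left + right
    starts = [a - left for a in anchors]
    if starts[0] < 0 or starts[-1] + rep_len > n:
        return None
    copies = [sequence[s:s + rep_len] for s in starts]
    # the majority-vote extension can step into the spacers when most
    # spacer-edge bases coincide by chance; trim boundary columns where
    # the copies disagree
    while rep_len > 0:
        if len({c[0] for c in copies}) > 1:
            starts = [s + 1 for s in starts]
            copies = [c[1:] for c in copies]
            rep_len -= 1
        elif len({c[-1] for c in copies}) > 1:
            copies = [c[:-1] for c in copies]
            rep_len -= 1
        else:
            break
    if not repeat_len_range[0] <= rep_len <= repeat_len_range[1]:
        return None
    consensus = _consensus(copies)
    for c in copies:
        if sum(1 for x, y in zip(c, consensus) if x != y) > max_repeat_mismatch:
            return None
    spacers = []
    for s0, s1 in zip(starts, starts[1:]):
        sp = sequence[s0 + rep_len:s1]
        if not spacer_len_range[0] <= len(sp) <= spacer_len_range[1]:
            return None
        spacers.append(sp)
    start = starts[0]
    end = starts[-1] + rep_len
    return CrisprArray(
        strain=strain, contig=contig, start=start, end=end,
        repeat=consensus, spacers=spacers, n_repeats=len(anchors),
        truncated=(start == 0 or end == n))


def find_arrays_in_genome(
    strain: str,
    contigs: Mapping[str, str],
    **kwargs,
) -> list[CrisprArray]:
    out = []
    for cid in sorted(contigs):
        out.extend(find_arrays(strain, cid, contigs[cid], **kwargs))
    return out


def _canonical(spacer: str) -> str:
    rc = reverse_complement(spacer)
    return min(spacer, rc)


def catalog_spacers(
    arrays: Sequence[CrisprArray],
    strains: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Deduplicated spacer catalogue (reverse-complement aware).

    Returns the spacer x strain incidence matrix (0/1) and a mapping of
    spacer id -> canonical sequence. Spacer ids are assigned in order of
    first appearance (strain-sorted, array order, spacer order). Passing
    ``strains`` forces columns for strains with no array (all zero).
    """
    id_of: dict[str, str] = {}
    seqs: dict[str, str] = {}
    incidence: dict[str, set[str]] = defaultdict(set)
    if strains is None:
        strains = sorted({a.strain for a in arrays})
    else:
        strains = sorted(strains)
    for a in sorted(arrays, key=lambda a: (a.strain, a.contig, a.start)):
        for sp in a.spacers:
            can = _canonical(sp)
            if can not in id_of:
                sid = f"SP{len(id_of):04d}"
                id_of[can] = sid
                seqs[sid] = can
            incidence[id_of[can]].add(a.strain)
    rows = {sid: [int(s in incidence[sid]) for s in strains]
            for sid in sorted(seqs)}
    m = pd.DataFrame.from_dict(rows, orient="index", columns=strains, dtype=int)
    return m, seqs


def assign_types(
    arrays_by_strain: Mapping[str, Sequence[CrisprArray]],
) -> dict[str, int]:
    """Type strains by exact ordered spacer content.

    Strains with identical ordered spacer lists (concatenated over their
    arrays, reverse-complement canonicalised) share a type; no array means
    type 0. Type ids follow first appearance in strain-sorted order.
    """
    type_of: dict[str, int] = {}
    known: dict[tuple[str, ...], int] = {}
    next_id = 1
    for strain in sorted(arrays_by_strain):
        arrays = sorted(arrays_by_strain[strain],
                        key=lambda a: (a.contig, a.start))
        spacers = tuple(_canonical(sp) for a in arrays for sp in a.spacers)
        if not spacers:
            type_of[strain] = 0
            continue
        if spacers not in known:
            known[spacers] = next_id
            next_id += 1
        type_of[strain] = known[spacers]
    return type_of


def arrays_frame(arrays: Sequence[CrisprArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.strain, a.contig, a.start, a.end, a.repeat, a.n_repeats,
          ";".join(a.spacers), int(a.truncated)) for a in arrays],
        columns=["strain", "contig", "start", "end", "repeat",
                 "n_repeats", "spacers", "truncated"])
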
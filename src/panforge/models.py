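"""Shared domain records."""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A located coding sequence on one strain's assembly.

    Coordinates are 0-based half-open on the contig; ``strand`` is '+' or
    '-'. ``protein`` is the translated product (no stop symbol).
    """

    gene_id: str
    strain: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str = ""
    annotation: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def stop_coord(self) -> int:
        """Strand-aware stop coordinate (translation end) on the contig."""
        return self.end if self.strand == "+" else self.start
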
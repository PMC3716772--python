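"""File formats: FASTA via Biopython, GFF3 CDS tracks, TSV tables.

Internal coordinates are 0-based half-open throughout the package; the
GFF3 1-based inclusive convention is applied only here, at the boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass(frozen=True)
class GffFeature:
    """One CDS line of a GFF3 predictor or annotation track."""

    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    feature_id: str
    source: str = "panforge"
    attributes: dict = dataclasses.field(default_factory=dict)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA (60-column wrap)."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, features: Iterable[GffFeature]) -> None:
    """Write CDS features as GFF3, converting to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = {"ID": f.feature_id, **f.attributes}
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{f.contig}\t{f.source}\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attr_s}\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Read CDS features from GFF3 back into 0-based half-open coordinates."""
    out: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = {}
            for kv in parts[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            fid = attrs.pop("ID", f"{parts[0]}:{parts[3]}-{parts[4]}")
            out.append(
                GffFeature(
                    contig=parts[0],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                    feature_id=fid,
                    source=parts[1],
                    attributes=attrs,
                )
            )
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(seq: str, table: int = 11) -> str:
    """Translate a CDS (already strand-corrected), trimming a stop codon."""
    prot = str(Seq(seq).translate(table=table))
    return prot[:-1] if prot.endswith("*") else prot
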
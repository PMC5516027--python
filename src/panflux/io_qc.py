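"""Sequence/annotation I/O and gene-set quality control.

Gene sets entering the comparative pipeline are screened with three rules
commonly applied to downloaded annotations:

1. proteins shorter than 50 aa are removed;
2. genes whose ORF contains an in-frame stop codon before the terminal codon
   are removed;
3. genes whose CDS contains more than 30% ambiguous bases (N) are removed.

A CDS whose length is not a multiple of 3 cannot be screened for internal
stops and is removed with its own ``frame-error`` tag, counted separately.
Records that carry only a protein (no CDS) are flagged ``cds-missing`` and
retained: rules 2-3 are defined on the CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .codons import STOP_CODONS

MIN_PROTEIN_AA = 50
MAX_N_FRACTION = 0.30


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass
class GeneRecord:
    """One protein-coding gene of one strain.

    Coordinates are 0-based half-open on ``contig``; ``cds`` is given on the
    coding strand (already reverse-complemented for ``strand == '-'``).
    """

    gene_id: str
    strain: str
    cds: str | None = None
    protein: str | None = None
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class GeneSet:
    strain: str
    records: list[GeneRecord] = field(default_factory=list)
    qc_flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in strain {self.strain}: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    An empty file yields an empty list. A file whose first non-blank line is
    not a header raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line!r}")
            break
    with open(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk; 0-based half-open in memory)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from a GFF3 file.

    Returns a DataFrame with 0-based half-open ``start``/``end`` plus an
    ``gene_id`` column extracted from the ID= attribute. Malformed lines raise
    :class:`ParseError` with the line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            try:
                start1 = int(parts[3])
                end1 = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            if parts[6] not in "+-.":
                raise ParseError(f"{path}:{lineno}: bad strand {parts[6]!r}")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if kv and "=" in kv
            )
            rows.append(
                {
                    "seqid": parts[0],
                    "source": parts[1],
                    "type": parts[2],
                    "start": start1 - 1,
                    "end": end1,
                    "strand": parts[6],
                    "gene_id": attrs.get("ID", f"line{lineno}"),
                }
            )
    return pd.DataFrame(rows, columns=["seqid", "source", "type", "start", "end", "strand", "gene_id"])


def write_gff3(genes: Sequence[GeneRecord], path: str | Path, source: str = "panflux") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def _protein_aa_length(protein: str) -> int:
    # a trailing '*' (terminal stop) does not count toward the 50-aa rule
    return len(protein.rstrip("*"))


def _has_internal_stop(cds: str) -> bool:
    cds = cds.upper()
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return True
    return False


def qc_rules(record: GeneRecord) -> list[str]:
    """Tags of every QC rule the record violates (empty list = clean pass)."""
    tags: list[str] = []
    protein = record.protein
    if protein is None and record.cds is not None and len(record.cds) % 3 == 0:
        protein = str(Seq(record.cds).translate())
    if protein is not None and _protein_aa_length(protein) < MIN_PROTEIN_AA:
        tags.append("short")
    if record.cds is None:
        tags.append("cds-missing")
        return tags
    if len(record.cds) % 3 != 0:
        tags.append("frame-error")
    else:
        if _has_internal_stop(record.cds):
            tags.append("internal-stop")
    n_frac = record.cds.upper().count("N") / len(record.cds) if record.cds else 0.0
    if n_frac > MAX_N_FRACTION:
        tags.append("high-n")
    return tags


_REMOVAL_TAGS = {"short", "internal-stop", "high-n", "frame-error"}


def filter_gene_set(gene_set: GeneSet) -> tuple[GeneSet, pd.DataFrame]:
    """Apply the three screening rules; returns (filtered set, rejection report).

    The report has one row per rejected gene with a comma-joined ``rules``
    column; ``cds-missing`` records are flagged but retained.
    """
    kept: list[GeneRecord] = []
    flags: dict[str, list[str]] = {}
    rows = []
    for rec in gene_set.records:
        tags = qc_rules(rec)
        if tags:
            flags[rec.gene_id] = tags
        if any(t in _REMOVAL_TAGS for t in tags):
            rows.append({"gene_id": rec.gene_id, "strain": rec.strain, "rules": ",".join(tags)})
        else:
            kept.append(rec)
    report = pd.DataFrame(rows, columns=["gene_id", "strain", "rules"])
    return GeneSet(strain=gene_set.strain, records=kept, qc_flags=flags), report
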
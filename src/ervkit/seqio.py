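"""Sequence and alignment I/O.

Reads and writes plain/aligned FASTA via Biopython, validates residues,
builds majority-rule consensus sequences, and applies the column-coverage
filter used to mask poorly covered alignment positions before distance
computation.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, EmptyAlignmentError, FormatError

#: Residues permitted in a validated record.
ALLOWED = set("ACGTN-")

#: Symbols that do not count as sequence coverage (gap and ambiguous base).
MISSING = set("N-")


@dataclass
class SequenceRecord:
    """A validated DNA sequence.

    Residues are upper-case over ``{A, C, G, T, N, -}``; ``U`` is mapped to
    ``T`` on construction so RNA-style input is accepted transparently.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """An ordered set of equal-length sequence records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}:{len(r)}" for r in self.records)
            raise AlignmentError(f"ragged record lengths: {detail}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.records)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        recs = [
            SequenceRecord(
                r.id, "".join(r.residues[i] for i in indices), r.description
            )
            for r in self.records
        ]
        return Alignment(recs)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Raises :class:`FormatError` on an empty file, duplicate ids, or illegal
    residue characters, naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    out = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (gap character ``-``) and validate lengths."""
    return Alignment(read_fasta(path))


def column_coverage(aln: Alignment, i: int) -> float:
    """Fraction of records with a non-gap, non-N symbol in column ``i``."""
    col = aln.column(i)
    return sum(1 for c in col if c not in MISSING) / len(col)


def filter_columns(aln: Alignment, min_coverage: float = 0.95) -> Alignment:
    """Keep exactly the columns with coverage >= ``min_coverage``.

    Coverage counts N as missing, alongside gaps. Column order is
    preserved; the operation is idempotent at a fixed threshold.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    keep = [
        i for i in range(aln.length) if column_coverage(aln, i) >= min_coverage
    ]
    if not keep:
        raise EmptyAlignmentError(
            f"coverage filter at {min_coverage} removed all {aln.length} columns"
        )
    return aln.take_columns(keep)


def consensus(aln: Alignment, id: str = "consensus") -> SequenceRecord:
    """Per-column strict-majority consensus.

    Gaps and N are treated as absent; a tie (or an all-missing column) is
    called N rather than picking a base arbitrarily, so downstream mutation
    censuses never see a fabricated direction.
    """
    out = []
    for i in range(aln.length):
        counts = Counter(c for c in aln.column(i) if c not in MISSING)
        if not counts:
            out.append("N")
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")
        else:
            out.append(ranked[0][0])
    return SequenceRecord(id, "".join(out))
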
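"""Protein sequence records with explicit residue numbering, plus FASTA I/O.

Every public API in this package addresses residues by *author numbering*:
1-based residue numbers, inclusive on both ends, anchored by the record's
``first_number``.  This lets a domain excised from a larger protein (e.g. the
GroEL apical domain, residues 192-333 of the full-length chaperonin) keep the
numbering used in the structural literature instead of restarting at 1.

The numbering offset travels with the sequence in a ``start=<n>`` token in the
FASTA header (a local dialect; absent means 1), so records round-trip through
files without losing their frame of reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The twenty standard one-letter amino-acid codes.  Non-standard letters
#: (X, U, B, Z, ...) are rejected: downstream per-residue scales have no
#: parameters for them.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_START_TOKEN = re.compile(r"(?:^|\s)start=(-?\d+)(?:\s|$)")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein chain with an explicit residue-numbering offset.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Uppercase one-letter sequence; only the 20 standard codes.
    first_number : int
        Residue number of the first character (default 1).
    """

    id: str
    residues: str
    first_number: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residue(s) "
                f"{', '.join(sorted(bad))!s} (only the 20 standard "
                "uppercase one-letter codes are accepted)"
            )

    @property
    def last_number(self) -> int:
        """Residue number of the final character (inclusive)."""
        return self.first_number + len(self.residues) - 1

    def __len__(self) -> int:
        return len(self.residues)

    def position_to_index(self, position: int) -> int:
        """Map an author residue number to a 0-based string index."""
        if not self.first_number <= position <= self.last_number:
            raise IndexError(
                f"position {position} outside record {self.id!r} "
                f"({self.first_number}..{self.last_number})"
            )
        return position - self.first_number

    def residue_at(self, position: int) -> str:
        """One-letter code at an author residue number."""
        return self.residues[self.position_to_index(position)]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    The numbering offset is parsed from a ``start=<n>`` token anywhere in the
    header; absent, it defaults to 1.  Whitespace and gap characters inside
    the sequence are stripped; letters are uppercased before validation.

    Raises
    ------
    ValueError
        If the file contains no records, or a sequence contains a character
        outside the 20 standard amino-acid codes.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        header = f"{entry.id} {entry.description}"
        m = _START_TOKEN.search(header)
        first_number = int(m.group(1)) if m else 1
        residues = re.sub(r"[\s\-.*]", "", str(entry.seq)).upper()
        records.append(SequenceRecord(entry.id, residues, first_number))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as 80-column-wrapped FASTA with ``start=<n>`` headers.

    Round-trips through :func:`read_fasta` to identical records.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    bio_records = [
        _BioSeqRecord(
            Seq(rec.residues),
            id=rec.id,
            description=f"start={rec.first_number}",
        )
        for rec in records
    ]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=80).write_file(bio_records)


def extract_region(record: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Extract residues ``start..end`` (author numbering, both ends inclusive).

    The returned record keeps author numbering: its ``first_number`` is
    ``start`` and its length is ``end - start + 1``.
    """
    if not (record.first_number <= start <= end <= record.last_number):
        raise ValueError(
            f"region {start}..{end} invalid for record {record.id!r}: "
            f"valid range is {record.first_number}..{record.last_number} "
            "with start <= end"
        )
    i = start - record.first_number
    j = end - record.first_number + 1
    return SequenceRecord(record.id, record.residues[i:j], first_number=start)
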
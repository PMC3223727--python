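"""Sequence records and FASTA I/O.

The universal currency of the pipeline is the :class:`SequenceRecord`: an
identified protein or nucleotide sequence. Records are validated against a
declared alphabet (20 amino acids plus X for proteins; ACGTN for
nucleotides) and stored uppercase. FASTA parsing is delegated to
Biopython's SeqIO; writing is done directly so that output bytes are
stable for a fixed line width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

Alphabet = Literal["protein", "nucleotide"]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_ALPHABETS = {"protein": PROTEIN_ALPHABET, "nucleotide": NUCLEOTIDE_ALPHABET}


class FastaError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, illegal residues)."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence over a declared alphabet.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a collection.
    residues : str
        Non-empty sequence; stored uppercase.
    alphabet : {"protein", "nucleotide"}
    description : str
        Free text carried after the id on the FASTA header.
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(residues):
            if ch not in allowed:
                raise FastaError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    """Raise :class:`FastaError` listing any duplicated record ids."""
    seen: set[str] = set()
    dups: list[str] = []
    for rec in records:
        if rec.id in seen and rec.id not in dups:
            dups.append(rec.id)
        seen.add(rec.id)
    if dups:
        raise FastaError(f"duplicate sequence ids: {', '.join(sorted(dups))}")


def read_fasta(path: str | Path, alphabet: Alphabet) -> List[SequenceRecord]:
    """Read a FASTA file into validated records, preserving input order.

    Raises :class:`FastaError` on duplicate ids or residues outside the
    declared alphabet. An empty file yields an empty list (with a warning).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=seqrec.id,
                residues=str(seqrec.seq),
                alphabet=alphabet,
                description=seqrec.description[len(seqrec.id) :].strip(),
            )
        )
    if not records:
        logger.warning("no FASTA records found in %s", path)
    check_unique_ids(records)
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; byte-stable for a fixed line width."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[i : i + line_width] + "\n")


def reverse_complement(record: SequenceRecord) -> SequenceRecord:
    """Reverse complement of a nucleotide record (N maps to N)."""
    if record.alphabet != "nucleotide":
        raise ValueError("reverse_complement requires a nucleotide record")
    table = str.maketrans("ACGTN", "TGCAN")
    return SequenceRecord(
        id=record.id,
        residues=record.residues.translate(table)[::-1],
        alphabet="nucleotide",
        description=record.description,
    )
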
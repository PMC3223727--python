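"""Local alignment primitive shared by every pipeline stage.

This module wraps an affine-gap Smith-Waterman (Biopython's
``PairwiseAligner`` in local mode) behind the small surface the pipeline
needs: a :class:`ScoringScheme` bundling substitution matrix, gap
penalties and Karlin-Altschul parameters, and :func:`local_align`
returning a :class:`AlignmentResult` with raw score, an E-value, spans
and identity counts.

Conventions
-----------
* Coordinates are 0-based half-open on the ungapped sequences.
* ``gap_open`` is the score of the first column of a gap and
  ``gap_extend`` of each subsequent column, so a gap of length L scores
  ``gap_open + (L - 1) * gap_extend``.
* Percent identity is identities over alignment columns (gap columns
  included), as BLAST reports it; an ``identities / shorter sequence``
  alternative is available where it matters (clustering).
* E-value: ``K * m * n * exp(-lambda * score)`` with m, n the full
  (unaligned) sequence lengths. The shipped protein defaults
  (lambda = 0.267, K = 0.041) are the standard gapped BLOSUM62 11/1
  values; thresholds, not absolute E-values, drive the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import SequenceRecord

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "local_align",
    "length_coverage",
    "protein_scheme",
    "nucleotide_scheme",
    "alignments_to_blast6",
]


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties, Karlin-Altschul params."""

    matrix: substitution_matrices.Array
    gap_open: int = -11
    gap_extend: int = -1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    alphabet: Literal["protein", "nucleotide"] = "protein"
    _aligner: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        arr = self.matrix
        if (arr != arr.transpose()).any():
            raise ValueError("substitution matrix must be symmetric")

    @property
    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            a = Align.PairwiseAligner()
            a.mode = "local"
            a.substitution_matrix = self.matrix
            a.open_gap_score = float(self.gap_open)
            a.extend_gap_score = float(self.gap_extend)
            self._aligner = a
        return self._aligner

    def score_only(self, query: str, subject: str) -> int:
        """Raw optimal local score without traceback (fast path)."""
        return int(round(self.aligner.score(query, subject)))


def protein_scheme(
    gap_open: int = -11,
    gap_extend: int = -1,
    karlin_lambda: float = 0.267,
    karlin_K: float = 0.041,
) -> ScoringScheme:
    """BLOSUM62 with BLASTP-default affine penalties."""
    return ScoringScheme(
        matrix=substitution_matrices.load("BLOSUM62"),
        gap_open=gap_open,
        gap_extend=gap_extend,
        karlin_lambda=karlin_lambda,
        karlin_K=karlin_K,
        alphabet="protein",
    )


def nucleotide_scheme(
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
    karlin_lambda: float = 1.28,
    karlin_K: float = 0.46,
) -> ScoringScheme:
    """Simple match/mismatch nucleotide scheme; N scores as a mismatch."""
    alphabet = "ACGTN"
    arr = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == y and x != "N":
                arr[x, y] = match
            else:
                arr[x, y] = mismatch
    return ScoringScheme(
        matrix=arr,
        gap_open=gap_open,
        gap_extend=gap_extend,
        karlin_lambda=karlin_lambda,
        karlin_K=karlin_K,
        alphabet="nucleotide",
    )


@dataclass(frozen=True)
class AlignmentResult:
    """A scored local alignment between two sequences.

    Spans are 0-based half-open intervals on the ungapped sequences.
    ``strand`` is "+" unless the caller aligned a reverse-complemented
    nucleotide query, in which case spans are reported on the forward
    strand of the query with ``strand == "-"``.
    """

    query_id: str
    subject_id: str
    score: int
    evalue: float
    aln_length: int
    identities: int
    mismatches: int
    gap_opens: int
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.identities > self.aln_length:
            raise ValueError("identities cannot exceed alignment length")
        for span in (self.query_span, self.subject_span):
            if span[1] - span[0] > self.aln_length or span[0] > span[1] or span[0] < 0:
                raise ValueError(f"invalid span {span}")
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")

    @property
    def percent_identity(self) -> float:
        """identities / alignment columns, in [0, 1]; 0 for empty alignments."""
        if self.aln_length == 0:
            return 0.0
        return self.identities / self.aln_length

    @property
    def bitscore(self) -> float:
        return 0.0 if self.aln_length == 0 else _bitscore(self.score, 0.267, 0.041)


def _bitscore(score: int, lam: float, K: float) -> float:
    return (lam * score - math.log(K)) / math.log(2)


def evalue_for_score(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul E-value for a raw score between lengths m and n."""
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * score)


def _gap_opens(tblocks, qblocks) -> int:
    opens = 0
    for i in range(1, len(tblocks)):
        if tblocks[i][0] > tblocks[i - 1][1]:
            opens += 1
        if qblocks[i][0] > qblocks[i - 1][1]:
            opens += 1
    return opens


def local_align(
    query: SequenceRecord, subject: SequenceRecord, scheme: ScoringScheme
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment of two records.

    Deterministic: among co-optimal alignments the engine's first
    traceback is reported. Raises on mixed alphabets or empty sequences.
    """
    if query.alphabet != subject.alphabet:
        raise ValueError(
            f"mixed alphabets: {query.id} is {query.alphabet}, "
            f"{subject.id} is {subject.alphabet}"
        )
    if query.alphabet != scheme.alphabet:
        raise ValueError("scoring scheme alphabet does not match the records")
    m, n = len(query), len(subject)
    alignments = scheme.aligner.align(query.residues, subject.residues)
    try:
        best = alignments[0]
    except (IndexError, ValueError):
        best = None
    if best is None or best.score <= 0 or len(best.aligned[0]) == 0:
        return AlignmentResult(
            query_id=query.id,
            subject_id=subject.id,
            score=0,
            evalue=evalue_for_score(0, m, n, scheme),
            aln_length=0,
            identities=0,
            mismatches=0,
            gap_opens=0,
            query_span=(0, 0),
            subject_span=(0, 0),
        )
    score = int(round(best.score))
    counts = best.counts()
    qblocks, sblocks = best.aligned
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        evalue=evalue_for_score(score, m, n, scheme),
        aln_length=counts.identities + counts.mismatches + counts.gaps,
        identities=counts.identities,
        mismatches=counts.mismatches,
        gap_opens=_gap_opens(qblocks, sblocks),
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]), int(sblocks[-1][1])),
    )


def length_coverage(
    aln: AlignmentResult,
    seq: SequenceRecord,
    which: Literal["query", "subject"],
) -> float:
    """Fraction of ``seq`` covered by the aligned span (0..1)."""
    if which == "query":
        if aln.query_id != seq.id:
            raise ValueError(f"alignment query {aln.query_id!r} != record {seq.id!r}")
        span = aln.query_span
    elif which == "subject":
        if aln.subject_id != seq.id:
            raise ValueError(
                f"alignment subject {aln.subject_id!r} != record {seq.id!r}"
            )
        span = aln.subject_span
    else:
        raise ValueError("which must be 'query' or 'subject'")
    return (span[1] - span[0]) / len(seq)


def alignments_to_blast6(alignments: Iterable[AlignmentResult]) -> pd.DataFrame:
    """Tab-separated BLAST "outfmt 6"-style table (1-based inclusive coords)."""
    rows = []
    for a in alignments:
        rows.append(
            {
                "qseqid": a.query_id,
                "sseqid": a.subject_id,
                "pident": round(100 * a.percent_identity, 2),
                "length": a.aln_length,
                "mismatch": a.mismatches,
                "gapopen": a.gap_opens,
                "qstart": a.query_span[0] + 1,
                "qend": a.query_span[1],
                "sstart": a.subject_span[0] + 1,
                "send": a.subject_span[1],
                "evalue": a.evalue,
                "bitscore": round(a.bitscore, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid",
            "sseqid",
            "pident",
            "length",
            "mismatch",
            "gapopen",
            "qstart",
            "qend",
            "sstart",
            "send",
            "evalue",
            "bitscore",
        ],
    )
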
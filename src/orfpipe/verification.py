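"""Structural verification of ORF models from sequencing reads.

Two complementary routes, mirroring how amplicon resequencing is used to
check predicted gene models:

* **Shotgun route** — raw reads are vector/tail-trimmed, length-filtered
  (< 20 nt dropped), mapped to the ORF reference sequences (>= 40 nt
  overlap, >= 90% identity), and each reference is classified from its
  per-base coverage: *verified* when more than 98% of its length is
  covered, otherwise binned at 95-100 / 50-95 / 20-50 / <20 percent.
* **End-read (OST) route** — a forward and reverse Sanger-style read per
  clone are merged on their overlap when possible; an ORF's 5' (3') end
  is confirmed when a read or the merged contig aligns across the first
  (last) reference base at >= 95% identity, and a full-length contig must
  additionally match >= 98% of the reference at >= 98% identity.

Read mapping uses edlib semi-global (infix) alignment, the standard
approach for aligning whole reads inside a longer reference; identity is
computed over alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .align import ScoringScheme, local_align, nucleotide_scheme
from .records import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

COVERAGE_BINS = ("95-100", "50-95", "20-50", "<20")


@dataclass(frozen=True)
class Read:
    """A sequencing read (shotgun amplicon read or Sanger-style end read)."""

    id: str
    nucleotides: str
    origin: Literal["shotgun", "end5", "end3"] = "shotgun"
    mate_orf_hint: Optional[str] = None

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.nucleotides, "nucleotide")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class MappingResult:
    """A read placed on a reference (forward-strand reference coordinates)."""

    read_id: str
    reference_id: str
    reference_span: Tuple[int, int]  # 0-based half-open
    identity: float
    strand: Literal["+", "-"]
    cigar: str = ""


@dataclass(frozen=True)
class CoverageProfile:
    reference_id: str
    depth: np.ndarray
    percent_covered: float

    def __post_init__(self) -> None:
        expected = 100.0 * np.count_nonzero(self.depth) / len(self.depth)
        if abs(expected - self.percent_covered) > 1e-9:
            raise ValueError("percent_covered inconsistent with depth array")


@dataclass(frozen=True)
class VerificationStatus:
    reference_id: str
    status: Literal["verified", "partial", "unsupported"]
    coverage_bin: Literal["95-100", "50-95", "20-50", "<20"]
    percent_covered: float


@dataclass(frozen=True)
class OSTVerification:
    reference_id: str
    five_prime_ok: bool
    three_prime_ok: bool
    both_ends_ok: bool
    full_length_contig: bool

    def __post_init__(self) -> None:
        if self.both_ends_ok and not (self.five_prime_ok and self.three_prime_ok):
            raise ValueError("both_ends_ok requires both single-end checks")
        if self.full_length_contig and not self.both_ends_ok:
            raise ValueError("full_length_contig requires both ends ok")


# ---------------------------------------------------------------------------
# trimming


def _find_contaminant_trim(
    read_seq: str,
    contaminant: SequenceRecord,
    scheme: ScoringScheme,
    min_identity: float,
    min_match_len: int,
    end_slack: int,
) -> Optional[Tuple[int, int]]:
    """New (start, end) of the read after one contaminant clip, or None."""
    rec = SequenceRecord("_read", read_seq, "nucleotide")
    for contam in (contaminant, reverse_complement(contaminant)):
        aln = local_align(contam, rec, scheme)
        span = aln.subject_span
        length = span[1] - span[0]
        if length < min_match_len or aln.percent_identity < min_identity:
            continue
        if span[0] <= end_slack:  # match at/near the 5' end: clip prefix
            return (span[1], len(read_seq))
        if span[1] >= len(read_seq) - end_slack:  # near the 3' end: clip suffix
            return (0, span[0])
    return None


def trim_reads(
    reads: Sequence[Read],
    contaminants: Sequence[SequenceRecord],
    min_len: int = 20,
    min_identity: float = 0.90,
    min_match_len: int = 10,
    end_slack: int = 5,
    scheme: ScoringScheme | None = None,
) -> List[Read]:
    """Clip vector/adapter contamination off read ends; drop short reads.

    Contaminant matches (local alignment at >= ``min_identity`` over
    >= ``min_match_len`` nt, within ``end_slack`` nt of a read end) are
    removed iteratively, so stacked vector+tail prefixes are fully
    clipped. Reads shorter than ``min_len`` after trimming are dropped
    (count logged).
    """
    scheme = scheme or nucleotide_scheme()
    kept: List[Read] = []
    dropped = 0
    for read in reads:
        seq = read.nucleotides
        changed = True
        while changed and len(seq) >= min_match_len:
            changed = False
            for contam in contaminants:
                clip = _find_contaminant_trim(
                    seq, contam, scheme, min_identity, min_match_len, end_slack
                )
                if clip is not None and clip != (0, len(seq)):
                    seq = seq[clip[0] : clip[1]]
                    changed = True
                    break
        if len(seq) < min_len:
            dropped += 1
            continue
        kept.append(replace(read, nucleotides=seq))
    if dropped:
        logger.info("trim_reads dropped %d read(s) shorter than %d nt", dropped, min_len)
    return kept


# ---------------------------------------------------------------------------
# mapping


def _cigar_length_and_read_ops(cigar: str) -> Tuple[int, int]:
    """(alignment columns, read-consuming columns) of an edlib cigar."""
    total = 0
    read_ops = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            total += n
            if ch in "=XI":
                read_ops += n
    return total, read_ops


def _map_one(
    read_seq: str, reference: SequenceRecord, min_identity: float
) -> Optional[Tuple[Tuple[int, int], float, str]]:
    # identity >= t over columns implies editDistance <= len(read) * (1-t)/t
    k = int(len(read_seq) * (1.0 - min_identity) / min_identity) + 1
    res = edlib.align(read_seq, reference.residues, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    start, end_incl = res["locations"][0]
    aln_len, _ = _cigar_length_and_read_ops(res["cigar"])
    identity = (aln_len - res["editDistance"]) / aln_len
    if identity < min_identity:
        return None
    return (start, end_incl + 1), identity, res["cigar"]


def map_reads(
    reads: Sequence[Read],
    references: Sequence[SequenceRecord],
    min_overlap: int = 40,
    min_identity: float = 0.90,
    mode: Literal["all", "best"] = "all",
) -> List[MappingResult]:
    """Align every read against every reference, both strands.

    A hit must span at least ``min_overlap`` nt of the read and reach
    ``min_identity`` over alignment columns. In ``all`` mode a read may
    map to several (paralogous) references; ``best`` keeps only its
    highest-identity reference (ties to the smaller reference id).
    """
    if not references:
        raise ValueError("empty reference set")
    results: List[MappingResult] = []
    for read in reads:
        if len(read) < min_overlap:
            continue
        fwd = read.nucleotides
        rev = reverse_complement(read.to_record()).residues
        per_read: List[MappingResult] = []
        for ref in references:
            best_hit: Optional[MappingResult] = None
            for strand, seq in (("+", fwd), ("-", rev)):
                hit = _map_one(seq, ref, min_identity)
                if hit is None:
                    continue
                span, identity, cigar = hit
                mr = MappingResult(read.id, ref.id, span, identity, strand, cigar)
                if best_hit is None or identity > best_hit.identity:
                    best_hit = mr
            if best_hit is not None:
                per_read.append(best_hit)
        if mode == "best" and per_read:
            per_read = [
                max(per_read, key=lambda m: (m.identity, m.reference_id))
            ]
        results.extend(sorted(per_read, key=lambda m: m.reference_id))
    return results


# ---------------------------------------------------------------------------
# coverage and classification


def coverage_profile(
    mappings: Sequence[MappingResult], reference: SequenceRecord
) -> CoverageProfile:
    """Per-base depth over a reference from its mapped read spans."""
    depth = np.zeros(len(reference), dtype=np.int64)
    for m in mappings:
        if m.reference_id != reference.id:
            continue
        start = max(0, m.reference_span[0])
        end = min(len(reference), m.reference_span[1])
        depth[start:end] += 1
    percent = 100.0 * np.count_nonzero(depth) / len(depth)
    return CoverageProfile(reference.id, depth, percent)


def classify_verification(
    profile: CoverageProfile, verified_min: float = 98.0
) -> VerificationStatus:
    """Classify a reference from its percent coverage.

    *verified* requires strictly more than 98% of the reference covered
    (98.0% exactly is not verified). Bins are [95,100], [50,95), [20,50),
    [0,20); references below 20% are called unsupported.
    """
    p = profile.percent_covered
    if p > verified_min:
        status = "verified"
    elif p >= 20.0:
        status = "partial"
    else:
        status = "unsupported"
    if p >= 95.0:
        cov_bin = "95-100"
    elif p >= 50.0:
        cov_bin = "50-95"
    elif p >= 20.0:
        cov_bin = "20-50"
    else:
        cov_bin = "<20"
    return VerificationStatus(profile.reference_id, status, cov_bin, p)


def coverage_histogram(statuses: Sequence[VerificationStatus]) -> Dict[str, int]:
    hist = {b: 0 for b in COVERAGE_BINS}
    for s in statuses:
        hist[s.coverage_bin] += 1
    return hist


def verification_table(statuses: Sequence[VerificationStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_id": s.reference_id,
                "percent_covered": round(s.percent_covered, 4),
                "status": s.status,
                "coverage_bin": s.coverage_bin,
            }
            for s in sorted(statuses, key=lambda s: s.reference_id)
        ],
        columns=["reference_id", "percent_covered", "status", "coverage_bin"],
    )


# ---------------------------------------------------------------------------
# OST (end-read) route


def assemble_ends(
    fwd: Read,
    rev: Read,
    min_overlap: int = 20,
    min_identity: float = 0.95,
) -> Optional[SequenceRecord]:
    """Merge a forward read with the reverse-complemented reverse read.

    The longest suffix of ``fwd`` matching a prefix of ``rc(rev)`` at
    >= ``min_identity`` (substitution-tolerant, position-wise comparison)
    and >= ``min_overlap`` nt defines the join; disagreements take the
    forward base. Returns None when no qualifying overlap exists
    (singlets).
    """
    f = fwd.nucleotides
    r = reverse_complement(rev.to_record()).residues
    for overlap in range(min(len(f), len(r)), min_overlap - 1, -1):
        f_tail = f[-overlap:]
        r_head = r[:overlap]
        matches = sum(1 for x, y in zip(f_tail, r_head) if x == y)
        if matches / overlap >= min_identity:
            contig_id = f"{fwd.mate_orf_hint or fwd.id}_contig"
            return SequenceRecord(contig_id, f + r[overlap:], "nucleotide")
    return None


def _end_alignment_ok(
    seq: SequenceRecord,
    reference: SequenceRecord,
    end: Literal["five", "three"],
    min_identity: float,
    scheme: ScoringScheme,
) -> bool:
    aln = local_align(seq, reference, scheme)
    if aln.aln_length == 0 or aln.percent_identity < min_identity:
        return False
    if end == "five":
        return aln.subject_span[0] == 0
    return aln.subject_span[1] == len(reference)


def verify_ost(
    fwd: Read,
    rev: Read,
    contig: Optional[SequenceRecord],
    reference_cds: SequenceRecord,
    min_end_identity: float = 0.95,
    full_length_identity: float = 0.98,
    full_length_coverage: float = 0.98,
) -> OSTVerification:
    """End-verify one ORF model from its clone's forward/reverse reads.

    The 5' end is confirmed when the forward read (or the assembled
    contig) aligns to the reference covering base 0; the 3' end
    analogously for the last base using the reverse-complemented reverse
    read (or contig). A full-length contig must exist, confirm both
    ends, and align over >= 98% of the reference at >= 98% identity.
    """
    scheme = nucleotide_scheme()
    five_candidates = [fwd.to_record()]
    three_candidates = [reverse_complement(rev.to_record())]
    if contig is not None:
        five_candidates.append(contig)
        three_candidates.append(contig)
    five_ok = any(
        _end_alignment_ok(c, reference_cds, "five", min_end_identity, scheme)
        for c in five_candidates
    )
    three_ok = any(
        _end_alignment_ok(c, reference_cds, "three", min_end_identity, scheme)
        for c in three_candidates
    )
    both = five_ok and three_ok
    full = False
    if contig is not None and both:
        aln = local_align(contig, reference_cds, scheme)
        span_frac = (aln.subject_span[1] - aln.subject_span[0]) / len(reference_cds)
        full = (
            aln.percent_identity >= full_length_identity
            and span_frac >= full_length_coverage
        )
    return OSTVerification(reference_cds.id, five_ok, three_ok, both, full)


def ost_table(items: Sequence[OSTVerification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_id": o.reference_id,
                "five_prime_ok": o.five_prime_ok,
                "three_prime_ok": o.three_prime_ok,
                "both_ends_ok": o.both_ends_ok,
                "full_length_contig": o.full_length_contig,
            }
            for o in sorted(items, key=lambda o: o.reference_id)
        ],
        columns=[
            "reference_id",
            "five_prime_ok",
            "three_prime_ok",
            "both_ends_ok",
            "full_length_contig",
        ],
    )


# ---------------------------------------------------------------------------
# SAM export


def _sam_cigar(m: MappingResult, read_len: int) -> str:
    """Convert an edlib cigar to SAM M/I/D ops; fall back to a bare match."""
    if not m.cigar:
        return f"{read_len}M"
    ops: List[Tuple[int, str]] = []
    num = ""
    for ch in m.cigar:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=X" else ch
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + int(num), op)
            else:
                ops.append((int(num), op))
            num = ""
    consumed = sum(n for n, op in ops if op in "MI")
    if consumed != read_len:  # orientation of I/D differs; swap
        ops = [(n, {"I": "D", "D": "I"}.get(op, op)) for n, op in ops]
    return "".join(f"{n}{op}" for n, op in ops)


def write_sam(
    mappings: Sequence[MappingResult],
    references: Sequence[SequenceRecord],
    reads: Sequence[Read],
    path: str | Path,
) -> None:
    """Minimal SAM export of read mappings (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in references],
    }
    ref_index = {r.id: i for i, r in enumerate(references)}
    read_by_id = {r.id: r for r in reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mappings:
            read = read_by_id[m.read_id]
            seq = read.nucleotides
            if m.strand == "-":
                seq = reverse_complement(read.to_record()).residues
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = m.read_id
            seg.query_sequence = seq
            seg.flag = 16 if m.strand == "-" else 0
            seg.reference_id = ref_index[m.reference_id]
            seg.reference_start = m.reference_span[0]
            seg.mapping_quality = 255
            seg.cigarstring = _sam_cigar(m, len(seq))
            out.write(seg)
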
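"""Read trimming, mapping, coverage classification, and OST verification."""

import numpy as np
import pytest

from orfpipe.records import SequenceRecord, reverse_complement
from orfpipe.verification import (
    CoverageProfile,
    MappingResult,
    OSTVerification,
    Read,
    assemble_ends,
    classify_verification,
    coverage_histogram,
    coverage_profile,
    map_reads,
    trim_reads,
    verify_ost,
    write_sam,
)

from .conftest import random_dna


def _ref(rng, length=500, rid="ref1"):
    return SequenceRecord(rid, random_dna(rng, length), "nucleotide")


TAIL = "AAAAAGCAGGCT"


# ---------------------------------------------------------------------------
# trimming


def test_tail_removed_insert_kept(rng):
    insert = random_dna(rng, 50)
    read = Read("r1", TAIL + insert)
    trimmed = trim_reads([read], [SequenceRecord("tail", TAIL, "nucleotide")])
    assert trimmed[0].nucleotides == insert


def test_short_after_trimming_dropped(rng):
    read = Read("r1", TAIL + random_dna(rng, 15))
    trimmed = trim_reads([read], [SequenceRecord("tail", TAIL, "nucleotide")])
    assert trimmed == []


def test_contaminant_free_read_unchanged(rng):
    seq = random_dna(rng, 80)
    trimmed = trim_reads(
        [Read("r1", seq)], [SequenceRecord("tail", TAIL, "nucleotide")]
    )
    assert trimmed[0].nucleotides == seq


def test_stacked_vector_and_tail_both_removed(rng):
    vector = random_dna(rng, 30)
    insert = random_dna(rng, 60)
    read = Read("r1", vector + TAIL + insert)
    trimmed = trim_reads(
        [read],
        [
            SequenceRecord("vec", vector, "nucleotide"),
            SequenceRecord("tail", TAIL, "nucleotide"),
        ],
    )
    assert trimmed[0].nucleotides == insert


# ---------------------------------------------------------------------------
# mapping


def test_exact_substring_maps(rng):
    ref = _ref(rng, 400)
    read = Read("r1", ref.residues[100:200])
    (m,) = map_reads([read], [ref])
    assert m.reference_span == (100, 200)
    assert m.identity == 1.0 and m.strand == "+"


def test_overlap_rule_39nt_rejected(rng):
    ref = _ref(rng, 400)
    assert map_reads([Read("r", ref.residues[10:49])], [ref]) == []
    assert len(map_reads([Read("r", ref.residues[10:50])], [ref])) == 1


def test_reverse_strand_mapping(rng):
    ref = _ref(rng, 300)
    fwd = SequenceRecord("x", ref.residues[50:150], "nucleotide")
    read = Read("r1", reverse_complement(fwd).residues)
    (m,) = map_reads([read], [ref])
    assert m.strand == "-" and m.reference_span == (50, 150)


def test_identity_threshold(rng):
    ref = _ref(rng, 400)
    sub = list(ref.residues[100:200])
    # mutate 15 of 100 positions: identity 0.85 < 0.90
    for i in range(0, 90, 6):
        sub[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[i]]
    assert map_reads([Read("r", "".join(sub))], [ref]) == []


def test_read_may_map_to_multiple_paralogs(rng):
    shared = random_dna(rng, 200)
    ref_a = SequenceRecord("a", shared + random_dna(rng, 100), "nucleotide")
    ref_b = SequenceRecord("b", shared + random_dna(rng, 150), "nucleotide")
    read = Read("r1", shared[20:120])
    hits = map_reads([read], [ref_a, ref_b])
    assert {m.reference_id for m in hits} == {"a", "b"}
    best = map_reads([read], [ref_a, ref_b], mode="best")
    assert len(best) == 1
    with pytest.raises(ValueError, match="empty reference"):
        map_reads([read], [])


# ---------------------------------------------------------------------------
# coverage


def test_coverage_profile_cases(rng):
    ref = _ref(rng, 100)
    assert coverage_profile([], ref).percent_covered == 0.0
    spans = [
        MappingResult("r1", "ref1", (0, 50), 1.0, "+"),
        MappingResult("r2", "ref1", (50, 100), 1.0, "+"),
    ]
    prof = coverage_profile(spans, ref)
    assert prof.percent_covered == 100.0
    assert prof.depth.sum() == 100


def test_coverage_monotone_under_read_addition(rng):
    ref = _ref(rng, 200)
    mappings = []
    last = 0.0
    for i in range(30):
        s = int(rng.integers(0, 160))
        e = s + int(rng.integers(10, 41))
        mappings.append(MappingResult(f"r{i}", "ref1", (s, min(e, 200)), 1.0, "+"))
        pct = coverage_profile(mappings, ref).percent_covered
        assert pct >= last
        last = pct


def test_coverage_order_and_duplicate_invariance(rng):
    ref = _ref(rng, 150)
    ms = [
        MappingResult(f"r{i}", "ref1", (int(s), int(s) + 30), 1.0, "+")
        for i, s in enumerate(rng.integers(0, 120, size=10))
    ]
    base = coverage_profile(ms, ref).percent_covered
    shuffled = [ms[i] for i in rng.permutation(10)]
    assert coverage_profile(shuffled, ref).percent_covered == base
    assert coverage_profile(ms + ms[:3], ref).percent_covered == base


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "percent,status,cov_bin",
    [
        (98.5, "verified", "95-100"),
        (98.0, "partial", "95-100"),  # strictly "more than 98%"
        (96.0, "partial", "95-100"),
        (70.0, "partial", "50-95"),
        (30.0, "partial", "20-50"),
        (10.0, "unsupported", "<20"),
        (0.0, "unsupported", "<20"),
    ],
)
def test_classification_bins(percent, status, cov_bin):
    depth = np.zeros(1000, dtype=np.int64)
    depth[: int(round(percent * 10))] = 1
    profile = CoverageProfile("ref", depth, percent)
    got = classify_verification(profile)
    assert (got.status, got.coverage_bin) == (status, cov_bin)


def test_histogram_counts_sum_to_reference_count(rng):
    statuses = []
    for i, pct in enumerate(rng.uniform(0, 100, size=25)):
        depth = np.zeros(200, dtype=np.int64)
        depth[: int(round(pct * 2))] = 1
        realized = 100.0 * np.count_nonzero(depth) / 200
        statuses.append(
            classify_verification(CoverageProfile(f"ref{i}", depth, realized))
        )
    hist = coverage_histogram(statuses)
    assert sum(hist.values()) == 25


# ---------------------------------------------------------------------------
# OST: end assembly and verification


def test_assemble_overlapping_ends(rng):
    ref = random_dna(rng, 1000)
    fwd = Read("f", ref[0:600], "end5")
    rev = Read(
        "r",
        reverse_complement(SequenceRecord("x", ref[500:1000], "nucleotide")).residues,
        "end3",
    )
    contig = assemble_ends(fwd, rev)
    assert contig is not None and contig.residues == ref


def test_non_overlapping_ends_are_singlets(rng):
    ref = random_dna(rng, 2000)
    fwd = Read("f", ref[0:600], "end5")
    rev = Read(
        "r",
        reverse_complement(SequenceRecord("x", ref[1400:2000], "nucleotide")).residues,
        "end3",
    )
    assert assemble_ends(fwd, rev) is None


def test_error_free_end_reads_verify_both_ends(rng):
    cds = random_dna(rng, 900)
    ref = SequenceRecord("orf1", cds, "nucleotide")
    fwd = Read("f", cds[0:600], "end5", mate_orf_hint="orf1")
    rev = Read(
        "r",
        reverse_complement(SequenceRecord("x", cds[300:900], "nucleotide")).residues,
        "end3",
        mate_orf_hint="orf1",
    )
    contig = assemble_ends(fwd, rev)
    result = verify_ost(fwd, rev, contig, ref)
    assert result.both_ends_ok and result.full_length_contig


def test_internal_forward_read_fails_five_prime(rng):
    cds = random_dna(rng, 900)
    ref = SequenceRecord("orf1", cds, "nucleotide")
    fwd = Read("f", cds[100:700], "end5")
    rev = Read(
        "r",
        reverse_complement(SequenceRecord("x", cds[300:900], "nucleotide")).residues,
        "end3",
    )
    result = verify_ost(fwd, rev, assemble_ends(fwd, rev), ref)
    assert not result.five_prime_ok
    assert result.three_prime_ok
    assert not result.both_ends_ok and not result.full_length_contig


def test_ost_invariants_enforced():
    with pytest.raises(ValueError):
        OSTVerification("r", False, True, True, False)
    with pytest.raises(ValueError):
        OSTVerification("r", True, True, False, True)


# ---------------------------------------------------------------------------
# SAM export


def test_sam_export_parses_back(tmp_path, rng):
    import pysam

    ref = _ref(rng, 300)
    reads = [Read("r1", ref.residues[40:160])]
    mappings = map_reads(reads, [ref])
    path = tmp_path / "out.sam"
    write_sam(mappings, [ref], reads, path)
    with pysam.AlignmentFile(str(path)) as sam:
        (rec,) = list(sam)
        assert rec.reference_name == "ref1"
        assert rec.reference_start == 40
        assert rec.query_alignment_length == 120
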
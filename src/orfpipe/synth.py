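"""Ground-truthed synthetic data with the statistical structure of the study.

The generator emulates, with known truth, every input the pipeline
consumes:

* an enzyme database of ancestor proteins, each with a distinct EC;
* a proteome organized into paralog families (point-mutated copies of
  the ancestors at a target identity) plus random decoy proteins;
* compartment-labelled reference/query protein sets whose amino-acid
  compositions carry Dirichlet-sampled, per-compartment biases, with
  independently perturbed plant and animal lineages;
* high-GC coding sequences (codon usage skewed toward a target G+C,
  0.64 by default, emulating a high-GC transcriptome);
* shotgun-style amplicon reads of variable depth with a heavy
  low-coverage tail (emulating low-expression transcripts) and a
  configurable zero-read fraction;
* vector/tail-contaminated paired end reads, with a configurable
  fraction of truncated clones to create end-verification failures.

Everything is deterministic: one global seed expands into fixed
per-stage child seeds, so identical (config, seed) gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import brentq

from .ec import EnzymeDbEntry
from .localization import COMPARTMENTS
from .primers import ATTB1_1_TAIL, ATTB2_1_TAIL
from .records import SequenceRecord, write_fasta
from .verification import Read

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed synthetic flanking-vector sequences (M13-primer-like ends plus filler)
VECTOR_5 = "TGTAAAACGACGGCCAGTCTTAAGCTCGGG"
VECTOR_3 = "CAGGAAACAGCTATGACCATGTAACGCGTC"

_STAGES = {
    "enzyme_db": 0,
    "proteome": 1,
    "compartments": 2,
    "cds": 3,
    "reads": 4,
    "end_reads": 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; defaults are the package's study conditions."""

    seed: int = 0
    # enzyme database / paralog families
    n_families: int = 20
    members_per_family: int = 5
    within_family_identity: float = 0.80
    n_decoys: int = 20
    ancestor_length_range: Tuple[int, int] = (150, 600)
    # compartment reference sets
    compartments: Tuple[str, ...] = COMPARTMENTS
    refs_per_compartment: int = 50
    queries_per_compartment: int = 10
    composition_bias: float = 0.9
    dirichlet_concentration: float = 0.5
    lineage_perturbation: float = 0.1
    ref_length_range: Tuple[int, int] = (100, 400)
    # coding sequences
    gc_content: float = 0.64
    # shotgun reads
    read_length_mean: float = 350.0
    read_length_sd: float = 60.0
    min_read_length: int = 40
    per_base_error: float = 0.01
    indel_rate: float = 0.0
    reads_per_orf_mean: float = 25.0
    reads_per_orf_shape: float = 2.0
    zero_read_fraction: float = 0.02
    # fraction of reads anchored at an amplicon end (nebulized fragments
    # include the terminal fragment of each molecule)
    anchor_end_fraction: float = 0.3
    # end reads
    end_read_length: int = 700
    end_read_error: float = 0.0
    truncated_clone_fraction: float = 0.10
    b1_tail: str = ATTB1_1_TAIL
    b2_tail: str = ATTB2_1_TAIL

    def __post_init__(self) -> None:
        for name in (
            "within_family_identity",
            "composition_bias",
            "per_base_error",
            "indel_rate",
            "zero_read_fraction",
            "truncated_clone_fraction",
            "gc_content",
            "end_read_error",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.within_family_identity == 0:
            raise ValueError("within_family_identity must be in (0, 1]")
        for name in ("n_families", "members_per_family", "refs_per_compartment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage child generator of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )


# ---------------------------------------------------------------------------
# proteins


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_protein(
    ancestor: str, identity: float, rng: np.random.Generator
) -> str:
    """Point-substitute each site with probability 1 - identity."""
    out = []
    for ch in ancestor:
        if rng.random() < 1.0 - identity:
            choices = AA20.replace(ch, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _synthetic_ec(i: int) -> str:
    return f"{i % 6 + 1}.{i % 9 + 1}.{i % 25 + 1}.{i + 1}"


def simulate_enzyme_db(cfg: SimulationConfig) -> List[EnzymeDbEntry]:
    """Random ancestor enzymes, one distinct synthetic EC each."""
    rng = cfg.rng("enzyme_db")
    lo, hi = cfg.ancestor_length_range
    entries = []
    for i in range(cfg.n_families):
        length = int(rng.integers(lo, hi + 1))
        acc = f"ENZ{i:04d}"
        entries.append(
            EnzymeDbEntry(
                accession=acc,
                record=SequenceRecord(acc, _random_protein(rng, length), "protein"),
                ec_numbers=(_synthetic_ec(i),),
            )
        )
    return entries


def simulate_proteome(
    db: Sequence[EnzymeDbEntry], cfg: SimulationConfig
) -> Tuple[List[SequenceRecord], pd.DataFrame]:
    """Paralog-family proteome derived from the ancestors, plus decoys.

    Returns the records and a truth table with columns
    ``orf_id, family_id, true_ec, is_decoy, realized_identity``.
    """
    rng = cfg.rng("proteome")
    records: List[SequenceRecord] = []
    rows = []
    counter = 0
    for fam_idx, entry in enumerate(db):
        for _ in range(cfg.members_per_family):
            orf_id = f"ORF{counter:05d}"
            counter += 1
            mutated = _mutate_protein(
                entry.record.residues, cfg.within_family_identity, rng
            )
            realized = sum(
                1 for a, b in zip(mutated, entry.record.residues) if a == b
            ) / len(mutated)
            records.append(SequenceRecord(orf_id, mutated, "protein"))
            rows.append(
                {
                    "orf_id": orf_id,
                    "family_id": fam_idx,
                    "true_ec": entry.ec_numbers[0],
                    "is_decoy": False,
                    "realized_identity": round(realized, 4),
                }
            )
    lo, hi = cfg.ancestor_length_range
    for _ in range(cfg.n_decoys):
        orf_id = f"DEC{counter:05d}"
        counter += 1
        length = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(orf_id, _random_protein(rng, length), "protein"))
        rows.append(
            {
                "orf_id": orf_id,
                "family_id": -1,
                "true_ec": "",
                "is_decoy": True,
                "realized_identity": float("nan"),
            }
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compartment reference sets


def _compartment_compositions(cfg: SimulationConfig, rng) -> Dict[str, np.ndarray]:
    uniform = np.full(20, 1 / 20)
    comps = {}
    for label in cfg.compartments:
        skew = rng.dirichlet(np.full(20, cfg.dirichlet_concentration))
        comps[label] = (1 - cfg.composition_bias) * uniform + cfg.composition_bias * skew
    return comps


def _perturb(base: np.ndarray, amount: float, rng) -> np.ndarray:
    return (1 - amount) * base + amount * rng.dirichlet(np.full(20, 1.0))


def _draw_protein(comp: np.ndarray, length: int, rng) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=comp))


def simulate_compartment_refs(
    cfg: SimulationConfig,
) -> Tuple[
    Dict[str, List[Tuple[SequenceRecord, str]]],
    List[Tuple[SequenceRecord, str]],
    pd.DataFrame,
]:
    """Labelled reference sets per lineage plus a held-out query set.

    Each compartment gets a composition mixing uniform with a Dirichlet
    draw at ``composition_bias`` (bias 0 makes compartments statistically
    indistinguishable). The plant and animal reference sets draw from
    independently perturbed versions of the base composition; queries
    draw from the base composition and carry the true label.
    """
    rng = cfg.rng("compartments")
    base = _compartment_compositions(cfg, rng)
    refs: Dict[str, List[Tuple[SequenceRecord, str]]] = {"plant": [], "animal": []}
    queries: List[Tuple[SequenceRecord, str]] = []
    rows = []
    lo, hi = cfg.ref_length_range
    for label in cfg.compartments:
        lineage_comp = {
            lineage: _perturb(base[label], cfg.lineage_perturbation, rng)
            for lineage in ("plant", "animal")
        }
        for lineage in ("plant", "animal"):
            for i in range(cfg.refs_per_compartment):
                rid = f"{lineage}_{label}_{i:04d}"
                length = int(rng.integers(lo, hi + 1))
                rec = SequenceRecord(
                    rid, _draw_protein(lineage_comp[lineage], length, rng), "protein"
                )
                refs[lineage].append((rec, label))
                rows.append(
                    {"protein_id": rid, "lineage": lineage, "compartment": label,
                     "role": "reference"}
                )
        for i in range(cfg.queries_per_compartment):
            qid = f"query_{label}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            rec = SequenceRecord(qid, _draw_protein(base[label], length, rng), "protein")
            queries.append((rec, label))
            rows.append(
                {"protein_id": qid, "lineage": "both", "compartment": label,
                 "role": "query"}
            )
    return refs, queries, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coding sequences


def _codon_map() -> Dict[str, List[Tuple[str, int]]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: Dict[str, List[Tuple[str, int]]] = {}
    for codon, aa in table.forward_table.items():
        gc = sum(1 for ch in codon if ch in "GC")
        by_aa.setdefault(aa, []).append((codon, gc))
    for codons in by_aa.values():
        codons.sort()
    return by_aa

_CODONS_BY_AA = _codon_map()
_STOPS = [("TAA", 0), ("TAG", 1), ("TGA", 1)]


def _softmax_weights(gcs: np.ndarray, beta: float) -> np.ndarray:
    w = np.exp(beta * (gcs - gcs.max()))
    return w / w.sum()


def _expected_gc(beta: float, aa_counts: Dict[str, int]) -> float:
    total_bases = 0.0
    total_gc = 0.0
    for aa, count in aa_counts.items():
        gcs = np.array([g for _, g in _CODONS_BY_AA[aa]], dtype=float)
        w = _softmax_weights(gcs, beta)
        total_gc += count * float((w * gcs).sum())
        total_bases += count * 3.0
    return total_gc / total_bases


def _calibrate_beta(aa_counts: Dict[str, int], target: float) -> float:
    """Codon-usage skew beta such that expected GC matches the target.

    Clamped to the achievable range (GC is bounded by the genetic code
    for a given amino-acid composition).
    """
    lo, hi = -30.0, 30.0
    if _expected_gc(hi, aa_counts) <= target:
        return hi
    if _expected_gc(lo, aa_counts) >= target:
        return lo
    return brentq(lambda b: _expected_gc(b, aa_counts) - target, lo, hi, xtol=1e-6)


def reverse_translate(
    protein: SequenceRecord,
    gc_content: float = 0.64,
    rng: np.random.Generator | int | None = None,
) -> SequenceRecord:
    """Back-translate a protein into a CDS with GC-skewed codon usage.

    Codons are sampled per residue with probability proportional to
    ``exp(beta * gc)`` where beta is calibrated against the protein's
    own amino-acid composition so the expected CDS G+C matches
    ``gc_content`` (clamped to what the genetic code permits). An ATG is
    the first codon (prepended when the protein does not start with M)
    and a stop codon is appended, so translating the CDS recovers the
    protein exactly.
    """
    if protein.alphabet != "protein":
        raise ValueError("reverse_translate needs a protein record")
    if "X" in protein.residues:
        raise ValueError(f"{protein.id}: cannot back-translate X residues")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    aa_counts: Dict[str, int] = {}
    for ch in protein.residues:
        aa_counts[ch] = aa_counts.get(ch, 0) + 1
    beta = _calibrate_beta(aa_counts, gc_content)
    codons: List[str] = []
    residues = protein.residues
    if residues[0] == "M":
        codons.append("ATG")
        residues = residues[1:]
    else:
        codons.append("ATG")
    for ch in residues:
        options = _CODONS_BY_AA[ch]
        gcs = np.array([g for _, g in options], dtype=float)
        w = _softmax_weights(gcs, beta)
        codons.append(options[rng.choice(len(options), p=w)][0])
    stop_gcs = np.array([g for _, g in _STOPS], dtype=float)
    w = _softmax_weights(stop_gcs, beta)
    codons.append(_STOPS[rng.choice(len(_STOPS), p=w)][0])
    return SequenceRecord(
        protein.id, "".join(codons), "nucleotide", description="synthetic CDS"
    )


def simulate_cds_set(
    proteome: Sequence[SequenceRecord], cfg: SimulationConfig
) -> List[SequenceRecord]:
    """Back-translate the whole proteome deterministically."""
    rng = cfg.rng("cds")
    return [reverse_translate(rec, cfg.gc_content, rng) for rec in proteome]


# ---------------------------------------------------------------------------
# reads


def _apply_errors(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return seq
    out = []
    bases = "ACGT"
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            continue  # deletion
        if sub_rate > 0 and rng.random() < sub_rate:
            alt = bases.replace(ch, "") if ch in bases else bases
            ch = alt[rng.integers(len(alt))]
        out.append(ch)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(bases[rng.integers(4)])  # insertion
    return "".join(out)


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_reads(
    cds_set: Sequence[SequenceRecord], cfg: SimulationConfig
) -> Tuple[List[Read], pd.DataFrame]:
    """Shotgun-style amplicon reads of variable depth per ORF.

    Per-ORF read counts are Gamma-Poisson (heavy low tail, so some ORFs
    are under-covered); a ``zero_read_fraction`` of ORFs yields no reads
    at all, emulating undetectably low expression.
    """
    rng = cfg.rng("reads")
    reads: List[Read] = []
    rows = []
    scale = cfg.reads_per_orf_mean / cfg.reads_per_orf_shape
    for cds in cds_set:
        L = len(cds)
        if rng.random() < cfg.zero_read_fraction:
            n = 0
        else:
            lam = rng.gamma(cfg.reads_per_orf_shape, scale)
            n = int(rng.poisson(lam))
        for i in range(n):
            raw_len = rng.normal(cfg.read_length_mean, cfg.read_length_sd)
            u = rng.random()
            if u < cfg.anchor_end_fraction / 2:  # left terminal fragment
                start = 0
            elif u < cfg.anchor_end_fraction:  # right terminal fragment
                start = max(0, L - int(np.clip(raw_len, cfg.min_read_length, L)))
            else:
                start = int(rng.integers(0, max(1, L - cfg.min_read_length)))
            length = int(
                np.clip(raw_len, cfg.min_read_length, L - start)
            )
            seq = cds.residues[start : start + length]
            seq = _apply_errors(seq, cfg.per_base_error, cfg.indel_rate, rng)
            if rng.random() < 0.5:
                seq = _rc(seq)
            reads.append(Read(f"{cds.id}_r{i:04d}", seq, "shotgun"))
        rows.append({"orf_id": cds.id, "n_reads": n})
    return reads, pd.DataFrame(rows)


def tile_reads(
    cds_set: Sequence[SequenceRecord], read_length: int = 120, step: int = 80
) -> List[Read]:
    """Error-free reads tiling every reference end to end (testing aid)."""
    reads = []
    for cds in cds_set:
        L = len(cds)
        starts = list(range(0, max(1, L - read_length + 1), step))
        if starts[-1] + read_length < L:
            starts.append(max(0, L - read_length))
        for i, s in enumerate(starts):
            reads.append(
                Read(f"{cds.id}_t{i:04d}", cds.residues[s : s + read_length], "shotgun")
            )
    return reads


def simulate_end_reads(
    cds_set: Sequence[SequenceRecord], cfg: SimulationConfig
) -> Tuple[List[Tuple[Read, Read]], pd.DataFrame]:
    """Paired vector/tail-contaminated end reads per cloned ORF.

    A ``truncated_clone_fraction`` of clones is shortened at a random
    end (10-30% of the CDS), creating downstream end-verification
    failures; the rest are full-length inserts. The forward read starts
    with a synthetic vector stub plus the B1.1 tail, the reverse read
    (on the reverse strand) with a vector stub plus the B2.1 tail.
    """
    rng = cfg.rng("end_reads")
    pairs: List[Tuple[Read, Read]] = []
    rows = []
    for cds in cds_set:
        truncated_end = "none"
        clone = cds.residues
        if rng.random() < cfg.truncated_clone_fraction:
            cut = int(len(clone) * rng.uniform(0.1, 0.3))
            cut = max(cut, 30)
            if rng.random() < 0.5:
                truncated_end = "5"
                clone = clone[cut:]
            else:
                truncated_end = "3"
                clone = clone[:-cut]
        fwd_prefix = VECTOR_5 + cfg.b1_tail
        rev_prefix = VECTOR_3 + cfg.b2_tail
        n_f = max(0, cfg.end_read_length - len(fwd_prefix))
        n_r = max(0, cfg.end_read_length - len(rev_prefix))
        fwd_seq = fwd_prefix + _apply_errors(
            clone[:n_f], cfg.end_read_error, 0.0, rng
        )
        rev_seq = rev_prefix + _apply_errors(
            _rc(clone)[:n_r], cfg.end_read_error, 0.0, rng
        )
        fwd = Read(f"{cds.id}_F", fwd_seq, "end5", mate_orf_hint=cds.id)
        rev = Read(f"{cds.id}_R", rev_seq, "end3", mate_orf_hint=cds.id)
        pairs.append((fwd, rev))
        rows.append(
            {
                "orf_id": cds.id,
                "truncated_end": truncated_end,
                "clone_full_length": truncated_end == "none",
            }
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-dataset generation and file emission


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus per-stage ground truth."""

    config: SimulationConfig
    enzyme_db: List[EnzymeDbEntry]
    proteome: List[SequenceRecord]
    proteome_truth: pd.DataFrame
    refs: Dict[str, List[Tuple[SequenceRecord, str]]]
    queries: List[Tuple[SequenceRecord, str]]
    localization_truth: pd.DataFrame
    cds_set: List[SequenceRecord]
    reads: List[Read]
    read_truth: pd.DataFrame
    end_read_pairs: List[Tuple[Read, Read]]
    clone_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> Dict[str, str]:
        """Emit the FASTA/TSV file set plus a manifest with checksums."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, outdir / "proteome.faa")
        write_fasta([e.record for e in self.enzyme_db], outdir / "enzymes.faa")
        pd.DataFrame(
            [
                {
                    "accession": e.accession,
                    "annotation": ";".join(e.ec_numbers + e.function_names),
                }
                for e in self.enzyme_db
            ]
        ).to_csv(outdir / "enzymes.tsv", sep="\t", index=False)
        for lineage in ("plant", "animal"):
            write_fasta(
                [rec for rec, _ in self.refs[lineage]],
                outdir / f"refs_{lineage}.faa",
            )
            pd.DataFrame(
                [
                    {"protein_id": rec.id, "compartment": label, "lineage": lineage}
                    for rec, label in self.refs[lineage]
                ]
            ).to_csv(outdir / f"refs_{lineage}.tsv", sep="\t", index=False)
        write_fasta([rec for rec, _ in self.queries], outdir / "queries.faa")
        write_fasta(self.cds_set, outdir / "orfs.fna")
        write_fasta(
            [r.to_record() for r in self.reads], outdir / "reads.fasta"
        )
        write_fasta(
            [f.to_record() for f, _ in self.end_read_pairs], outdir / "ends_5.fasta"
        )
        write_fasta(
            [r.to_record() for _, r in self.end_read_pairs], outdir / "ends_3.fasta"
        )
        self.proteome_truth.to_csv(outdir / "truth_orfs.tsv", sep="\t", index=False)
        self.localization_truth.to_csv(
            outdir / "truth_localization.tsv", sep="\t", index=False
        )
        self.read_truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.clone_truth.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
        checksums = {}
        for path in sorted(outdir.iterdir()):
            if path.name == "manifest.json" or path.is_dir():
                continue
            checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = {
            "config": dataclasses.asdict(self.config),
            "checksums": checksums,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return checksums


def generate(cfg: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage for one config."""
    db = simulate_enzyme_db(cfg)
    proteome, proteome_truth = simulate_proteome(db, cfg)
    refs, queries, loc_truth = simulate_compartment_refs(cfg)
    cds_set = simulate_cds_set(proteome, cfg)
    reads, read_truth = simulate_reads(cds_set, cfg)
    pairs, clone_truth = simulate_end_reads(cds_set, cfg)
    return SimulatedDataset(
        config=cfg,
        enzyme_db=db,
        proteome=proteome,
        proteome_truth=proteome_truth,
        refs=refs,
        queries=queries,
        localization_truth=loc_truth,
        cds_set=cds_set,
        reads=reads,
        read_truth=read_truth,
        end_read_pairs=pairs,
        clone_truth=clone_truth,
    )
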
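"""End-to-end orchestration: simulate, annotate, localize, design primers,
verify, and report.

:class:`PipelineConfig` aggregates every stage threshold, defaulting to
the pipeline's canonical constants (RBH E-value 1e-3; clustering 35%
identity / 70% coverage; k = 32 neighbors; 50% primary binning; 85%
consolidation cutoff; 40 nt / 90% read mapping; > 98% coverage for
verification; 20 nt read-length filter; 55-65 degC primer Tm).
:func:`run` executes the enabled stages in dependency order against a
run directory, exchanging data through the on-disk FASTA/TSV formats so
every reader/writer pair is exercised, and writes a deterministic
``summary.json`` (identical config and seed give byte-identical output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

from . import __version__
from .align import protein_scheme
from .ec import annotate_proteome, assignments_table, load_enzyme_db
from .localization import (
    COMPARTMENTS,
    bin_primary,
    compartment_frequencies,
    consolidate,
    consolidated_table,
    fit_reference_knn,
    predict_record,
    predictions_table,
)
from .primers import design_many, primer_table
from .records import SequenceRecord, read_fasta
from .synth import VECTOR_3, VECTOR_5, SimulationConfig, generate
from .verification import (
    Read,
    assemble_ends,
    classify_verification,
    coverage_histogram,
    coverage_profile,
    map_reads,
    ost_table,
    trim_reads,
    verification_table,
    verify_ost,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "annotate", "localize", "primers", "verify", "ost", "report")


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage toggles and thresholds; defaults are the canonical values."""

    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    data_dir: str | None = None  # use pre-generated inputs instead of simulate
    # annotation
    evalue_max: float = 1e-3
    identity_min: float = 0.35
    coverage_min: float = 0.70
    # localization
    knn_k: int = 32
    primary_threshold: float = 0.50
    consolidation_cutoff: float = 0.85
    knn_weighting: str = "uniform"
    # verification
    min_overlap: int = 40
    map_identity: float = 0.90
    verified_percent: float = 98.0
    trim_min_len: int = 20
    # primer design
    tm_min: float = 55.0
    tm_max: float = 65.0
    # simulation
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML mapping (nested ``sim``)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    for tup_key in ("ancestor_length_range", "ref_length_range", "compartments"):
        if tup_key in sim_raw:
            sim_raw[tup_key] = tuple(sim_raw[tup_key])
    return PipelineConfig(sim=SimulationConfig(**sim_raw), **raw)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input {path}")
    return path


def _load_labelled(
    data: Path, lineage: str, stage: str
) -> List[Tuple[SequenceRecord, str]]:
    recs = {
        r.id: r for r in read_fasta(_require(data / f"refs_{lineage}.faa", stage), "protein")
    }
    table = pd.read_csv(data / f"refs_{lineage}.tsv", sep="\t", dtype=str)
    return [(recs[row.protein_id], row.compartment) for row in table.itertuples()]


def _stage_annotate(cfg: PipelineConfig, data: Path, outdir: Path) -> Dict:
    proteome = read_fasta(_require(data / "proteome.faa", "annotate"), "protein")
    db = load_enzyme_db(
        _require(data / "enzymes.faa", "annotate"),
        _require(data / "enzymes.tsv", "annotate"),
    )
    assignments, clusters = annotate_proteome(
        proteome,
        db,
        protein_scheme(),
        evalue_max=cfg.evalue_max,
        identity_min=cfg.identity_min,
        coverage_min=cfg.coverage_min,
    )
    table = assignments_table(assignments, clusters)
    table.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    distinct_ecs = sorted(
        {ec for a in assignments for ec in a.ec_numbers}
    )
    counts = {
        "n_orfs_input": len(proteome),
        "n_orfs_annotated": len(assignments),
        "n_direct": sum(1 for a in assignments if a.provenance == "rbh_direct"),
        "n_propagated": sum(
            1 for a in assignments if a.provenance == "paralog_propagated"
        ),
        "n_distinct_ecs": len(distinct_ecs),
        "n_clusters": len(clusters),
    }
    truth_path = data / "truth_orfs.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        annotated = {a.orf_id: set(a.ec_numbers) for a in assignments}
        members = truth[~truth.is_decoy]
        correct = sum(
            1
            for row in members.itertuples()
            if row.true_ec in annotated.get(row.orf_id, set())
        )
        decoys = truth[truth.is_decoy]
        counts["ec_recovery_percent"] = round(100.0 * correct / len(members), 2)
        counts["n_decoys_annotated"] = sum(
            1 for row in decoys.itertuples() if row.orf_id in annotated
        )
    return counts


def _stage_localize(cfg: PipelineConfig, data: Path, outdir: Path) -> Dict:
    queries = read_fasta(_require(data / "queries.faa", "localize"), "protein")
    preds = {}
    for lineage in ("plant", "animal"):
        refs = _load_labelled(data, lineage, "localize")
        model = fit_reference_knn(refs, k=cfg.knn_k, weighting=cfg.knn_weighting)
        preds[lineage] = [predict_record(model, q, lineage) for q in queries]
        predictions_table(preds[lineage]).to_csv(
            outdir / f"localization_{lineage}.tsv", sep="\t", index=False
        )
        compartment_frequencies(preds[lineage]).to_csv(
            outdir / f"localization_bins_{lineage}.tsv", sep="\t", index=False
        )
    consolidated = [
        consolidate(p, a, cutoff=cfg.consolidation_cutoff)
        for p, a in zip(preds["plant"], preds["animal"])
    ]
    consolidated_table(consolidated).to_csv(
        outdir / "localization_consolidated.tsv", sep="\t", index=False
    )
    counts = {
        "n_queries": len(queries),
        "n_consolidated_assigned": sum(
            1 for c in consolidated if c.assignment != "other"
        ),
        "primary_bins_plant": {
            c: sum(1 for p in preds["plant"] if bin_primary(p, cfg.primary_threshold) == c)
            for c in (*COMPARTMENTS, "other")
        },
    }
    truth_path = data / "truth_localization.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", dtype=str)
        true_of = dict(
            zip(truth[truth.role == "query"].protein_id, truth[truth.role == "query"].compartment)
        )
        correct = sum(
            1 for p in preds["plant"] if p.top[0] == true_of.get(p.orf_id)
        )
        counts["plant_knn_accuracy_percent"] = round(
            100.0 * correct / len(queries), 2
        )
    return counts


def _stage_primers(cfg: PipelineConfig, data: Path, outdir: Path) -> Dict:
    cds_set = read_fasta(_require(data / "orfs.fna", "primers"), "nucleotide")
    pairs, failures = design_many(cds_set, tm_min=cfg.tm_min, tm_max=cfg.tm_max)
    primer_table(pairs, failures).to_csv(outdir / "primers.tsv", sep="\t", index=False)
    return {"n_primer_pairs": len(pairs), "n_primer_failures": len(failures)}


def _contaminants(cfg: PipelineConfig) -> List[SequenceRecord]:
    return [
        SequenceRecord("vector5", VECTOR_5, "nucleotide"),
        SequenceRecord("vector3", VECTOR_3, "nucleotide"),
        SequenceRecord("b1_tail", cfg.sim.b1_tail, "nucleotide"),
        SequenceRecord("b2_tail", cfg.sim.b2_tail, "nucleotide"),
    ]


def _stage_verify(cfg: PipelineConfig, data: Path, outdir: Path) -> Dict:
    references = read_fasta(_require(data / "orfs.fna", "verify"), "nucleotide")
    raw = [
        Read(r.id, r.residues, "shotgun")
        for r in read_fasta(_require(data / "reads.fasta", "verify"), "nucleotide")
    ]
    reads = trim_reads(raw, _contaminants(cfg), min_len=cfg.trim_min_len)
    mappings = map_reads(
        reads, references, min_overlap=cfg.min_overlap, min_identity=cfg.map_identity
    )
    by_ref: Dict[str, List] = {}
    for m in mappings:
        by_ref.setdefault(m.reference_id, []).append(m)
    statuses = [
        classify_verification(
            coverage_profile(by_ref.get(ref.id, []), ref), cfg.verified_percent
        )
        for ref in references
    ]
    verification_table(statuses).to_csv(
        outdir / "verification.tsv", sep="\t", index=False
    )
    hist = coverage_histogram(statuses)
    pd.DataFrame(
        [{"coverage_bin": b, "n": n} for b, n in hist.items()]
    ).to_csv(outdir / "verification_histogram.tsv", sep="\t", index=False)
    return {
        "n_references": len(references),
        "n_reads_kept": len(reads),
        "n_reads_raw": len(raw),
        "n_mappings": len(mappings),
        "n_verified": sum(1 for s in statuses if s.status == "verified"),
        "coverage_histogram": hist,
    }


def _stage_ost(cfg: PipelineConfig, data: Path, outdir: Path) -> Dict:
    references = {
        r.id: r for r in read_fasta(_require(data / "orfs.fna", "ost"), "nucleotide")
    }
    fwd_reads = read_fasta(_require(data / "ends_5.fasta", "ost"), "nucleotide")
    rev_reads = read_fasta(_require(data / "ends_3.fasta", "ost"), "nucleotide")
    contaminants = _contaminants(cfg)
    results = []
    for f_rec, r_rec in zip(fwd_reads, rev_reads):
        orf_id = f_rec.id.rsplit("_", 1)[0]
        if orf_id not in references:
            raise StageError("ost", f"end read {f_rec.id} has no reference")
        fwd = Read(f_rec.id, f_rec.residues, "end5", mate_orf_hint=orf_id)
        rev = Read(r_rec.id, r_rec.residues, "end3", mate_orf_hint=orf_id)
        trimmed = trim_reads([fwd, rev], contaminants, min_len=cfg.trim_min_len)
        if len(trimmed) < 2:  # an end read lost entirely to trimming
            results.append(
                verify_ost(fwd, rev, None, references[orf_id])
            )
            continue
        fwd_t, rev_t = trimmed
        contig = assemble_ends(fwd_t, rev_t)
        results.append(verify_ost(fwd_t, rev_t, contig, references[orf_id]))
    ost_table(results).to_csv(outdir / "ost.tsv", sep="\t", index=False)
    return {
        "n_clones": len(results),
        "n_five_prime_ok": sum(1 for r in results if r.five_prime_ok),
        "n_three_prime_ok": sum(1 for r in results if r.three_prime_ok),
        "n_both_ends_ok": sum(1 for r in results if r.both_ends_ok),
        "n_full_length_contigs": sum(1 for r in results if r.full_length_contig),
    }


def run(cfg: PipelineConfig, outdir: str | Path) -> Dict:
    """Execute the enabled stages in dependency order; return the summary.

    The summary (also written as ``summary.json``) contains the headline
    tallies of each stage; re-running with the same config and seed
    reproduces it byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    summary: Dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(cfg.stages),
    }
    with log_path.open("w") as log:
        log.write(f"orfpipe {__version__}\n")
        log.write(f"seed {cfg.seed}\nconfig_hash {cfg.config_hash()}\n")
        defaults = PipelineConfig()
        for f in dataclasses.fields(PipelineConfig):
            if f.name in ("sim", "stages"):
                continue
            current = getattr(cfg, f.name)
            if current != getattr(defaults, f.name):
                log.write(f"override {f.name}={current}\n")

        needs_data = any(
            s in cfg.stages for s in ("annotate", "localize", "primers", "verify", "ost")
        )
        data = outdir / "data"
        if "simulate" in cfg.stages:
            sim_cfg = replace(cfg.sim, seed=cfg.seed)
            generate(sim_cfg).write(data)
            log.write(f"simulate -> {data}\n")
        elif cfg.data_dir is not None:
            data = Path(cfg.data_dir)
        elif needs_data:
            raise StageError("simulate", "stage disabled and no data_dir given")

        stage_fns = {
            "annotate": _stage_annotate,
            "localize": _stage_localize,
            "primers": _stage_primers,
            "verify": _stage_verify,
            "ost": _stage_ost,
        }
        for stage in ("annotate", "localize", "primers", "verify", "ost"):
            if stage not in cfg.stages:
                continue
            try:
                summary[stage] = stage_fns[stage](cfg, data, outdir)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate failure with stage
                raise StageError(stage, str(exc)) from exc
            log.write(f"{stage} done\n")

    if "report" in cfg.stages:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
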
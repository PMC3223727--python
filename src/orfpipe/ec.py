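"""Enzyme (EC) function transfer by reciprocal best hits plus paralog propagation.

The annotation stage has two steps. First, every ORF protein is compared
against an EC-labelled enzyme database and reciprocal best hits (each
sequence the other's top-scoring match at E-value <= 1e-3) transfer the
database entry's EC numbers onto the ORF. Second, the full proteome is
clustered single-linkage — an edge joins two proteins when a local
alignment reaches >= 35% identity with >= 70% length coverage — and EC
numbers of directly annotated cluster members are propagated to their
unannotated paralogs.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Literal, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .align import (
    AlignmentResult,
    ScoringScheme,
    evalue_for_score,
    length_coverage,
    local_align,
)
from .records import SequenceRecord, check_unique_ids, read_fasta

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

Provenance = Literal["rbh_direct", "paralog_propagated"]


@dataclass(frozen=True)
class EnzymeDbEntry:
    """A reference enzyme: protein sequence plus its EC numbers.

    Entries in the ``aracyc_like`` style may carry a free-text enzyme
    name instead of (or in addition to) EC numbers; those are counted
    separately downstream, mirroring databases that annotate enzymatic
    function without a formal EC assignment.
    """

    accession: str
    record: SequenceRecord
    ec_numbers: Tuple[str, ...]
    source: Literal["uniprot_like", "aracyc_like"] = "uniprot_like"
    function_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ec_numbers and not self.function_names:
            raise ValueError(
                f"{self.accession}: entry needs an EC number or a function name"
            )
        for ec in self.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"{self.accession}: malformed EC number {ec!r}")


@dataclass(frozen=True)
class ParalogCluster:
    cluster_id: int
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")


@dataclass(frozen=True)
class ECAssignment:
    orf_id: str
    ec_numbers: Tuple[str, ...]
    provenance: Provenance
    best_hit_accession: str | None = None
    cluster_id: int | None = None
    function_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.provenance == "rbh_direct" and self.best_hit_accession is None:
            raise ValueError(f"{self.orf_id}: direct assignment needs a best hit")
        if not self.ec_numbers and not self.function_names:
            raise ValueError(f"{self.orf_id}: empty annotation")


def load_enzyme_db(fasta_path: str | Path, tsv_path: str | Path) -> List[EnzymeDbEntry]:
    """Load an enzyme database from FASTA plus a two-column annotation TSV.

    The TSV has columns ``accession`` and ``annotation``; the annotation
    field is a semicolon-joined list in which tokens matching the EC
    pattern become EC numbers and any other token is kept as a free-text
    function name (``aracyc_like`` source: curated pathway databases
    often annotate enzymatic function without a formal EC).
    """
    records = {r.id: r for r in read_fasta(fasta_path, "protein")}
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    entries = []
    for row in table.itertuples(index=False):
        acc = row.accession
        if acc not in records:
            raise ValueError(f"enzyme TSV accession {acc!r} missing from FASTA")
        tokens = [t.strip() for t in str(row.annotation).split(";") if t.strip()]
        ecs = tuple(t for t in tokens if EC_PATTERN.match(t))
        names = tuple(t for t in tokens if not EC_PATTERN.match(t))
        source = "uniprot_like" if ecs else "aracyc_like"
        entries.append(
            EnzymeDbEntry(
                accession=acc,
                record=records[acc],
                ec_numbers=ecs,
                source=source,
                function_names=names,
            )
        )
    return entries


def _score_matrix(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    scheme: ScoringScheme,
) -> np.ndarray:
    scores = np.zeros((len(queries), len(targets)), dtype=np.int64)
    for i, q in enumerate(queries):
        for j, t in enumerate(targets):
            scores[i, j] = scheme.score_only(q.residues, t.residues)
    return scores


def _best_from_scores(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    scores: np.ndarray,
    scheme: ScoringScheme,
    evalue_max: float,
) -> Dict[str, str]:
    """Per query: qualifying (E <= max) target with highest raw score.

    Score ties break to the lexicographically smallest target id.
    """
    best: Dict[str, str] = {}
    for i, q in enumerate(queries):
        top: Tuple[int, str] | None = None
        for j, t in enumerate(targets):
            s = int(scores[i, j])
            if evalue_for_score(s, len(q), len(t), scheme) > evalue_max:
                continue
            if top is None or s > top[0] or (s == top[0] and t.id < top[1]):
                top = (s, t.id)
        if top is not None:
            best[q.id] = top[1]
    return best


def best_hits(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    evalue_max: float = 1e-3,
) -> Dict[str, Tuple[str, AlignmentResult]]:
    """Top-scoring database hit per query at the E-value threshold.

    Queries with no qualifying hit are absent from the result.
    """
    if not targets:
        raise ValueError("empty target set")
    check_unique_ids(queries)
    check_unique_ids(targets)
    by_id = {t.id: t for t in targets}
    scores = _score_matrix(queries, targets, scheme)
    chosen = _best_from_scores(queries, targets, scores, scheme, evalue_max)
    out: Dict[str, Tuple[str, AlignmentResult]] = {}
    for q in queries:
        if q.id in chosen:
            t = by_id[chosen[q.id]]
            out[q.id] = (t.id, local_align(q, t, scheme))
    return out


def reciprocal_best_hits(
    proteome: Sequence[SequenceRecord],
    enzyme_db: Sequence[EnzymeDbEntry],
    scheme: ScoringScheme,
    evalue_max: float = 1e-3,
) -> List[Tuple[str, str]]:
    """ORF/accession pairs that are each other's best hit.

    The E-value threshold is applied in both directions. The pairwise
    score matrix is computed once (the substitution matrix is symmetric,
    so scores are direction-independent).
    """
    if not enzyme_db:
        raise ValueError("empty enzyme database")
    db_records = [e.record for e in enzyme_db]
    acc_of = {e.record.id: e.accession for e in enzyme_db}
    scores = _score_matrix(proteome, db_records, scheme)
    fwd = _best_from_scores(proteome, db_records, scores, scheme, evalue_max)
    rev = _best_from_scores(db_records, proteome, scores.T, scheme, evalue_max)
    pairs = []
    for orf_id, db_id in fwd.items():
        if rev.get(db_id) == orf_id:
            pairs.append((orf_id, acc_of[db_id]))
    return sorted(pairs)


def transfer_ec(
    rbh_pairs: Sequence[Tuple[str, str]],
    enzyme_db: Sequence[EnzymeDbEntry],
) -> List[ECAssignment]:
    """One direct assignment per RBH pair, carrying all ECs of the entry."""
    by_acc = {e.accession: e for e in enzyme_db}
    assignments = []
    for orf_id, acc in rbh_pairs:
        entry = by_acc[acc]
        assignments.append(
            ECAssignment(
                orf_id=orf_id,
                ec_numbers=entry.ec_numbers,
                provenance="rbh_direct",
                best_hit_accession=acc,
                function_names=entry.function_names,
            )
        )
    return assignments


def _cluster_edge(
    a: SequenceRecord,
    b: SequenceRecord,
    scheme: ScoringScheme,
    identity_min: float,
    coverage_min: float,
    coverage_mode: Literal["both", "shorter"],
    pident_mode: Literal["columns", "shorter"],
) -> bool:
    aln = local_align(a, b, scheme)
    if aln.aln_length == 0:
        return False
    if pident_mode == "columns":
        pident = aln.percent_identity
    else:
        pident = aln.identities / min(len(a), len(b))
    if pident < identity_min:
        return False
    cov_a = length_coverage(aln, a, "query")
    cov_b = length_coverage(aln, b, "subject")
    if coverage_mode == "both":
        return cov_a >= coverage_min and cov_b >= coverage_min
    shorter_cov = cov_a if len(a) <= len(b) else cov_b
    return shorter_cov >= coverage_min


def cluster_paralogs(
    proteome: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    identity_min: float = 0.35,
    coverage_min: float = 0.70,
    coverage_mode: Literal["both", "shorter"] = "both",
    pident_mode: Literal["columns", "shorter"] = "columns",
) -> List[ParalogCluster]:
    """Single-linkage clustering of the proteome at identity/coverage cutoffs.

    An undirected edge joins two proteins when their optimal local
    alignment reaches ``identity_min`` percent identity and covers at
    least ``coverage_min`` of both sequences (``coverage_mode="shorter"``
    relaxes this to the shorter sequence only). Clusters are the
    connected components, so below-threshold pairs can still share a
    cluster through an above-threshold intermediate. Singletons are
    clusters of size one. Output is order-independent: clusters are
    sorted by their smallest member id.
    """
    check_unique_ids(proteome)
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in proteome)
    ordered = sorted(proteome, key=lambda r: r.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if _cluster_edge(
                a, b, scheme, identity_min, coverage_min, coverage_mode, pident_mode
            ):
                graph.add_edge(a.id, b.id)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    return [
        ParalogCluster(cluster_id=i, members=frozenset(comp))
        for i, comp in enumerate(components)
    ]


def propagate_ec(
    clusters: Sequence[ParalogCluster],
    direct_assignments: Sequence[ECAssignment],
) -> List[ECAssignment]:
    """Extend direct assignments to unannotated cluster members.

    Every unannotated member of a cluster containing at least one direct
    assignment receives the union of the cluster's direct EC sets (and
    function names). Direct assignments are returned unchanged, tagged
    with their cluster id. Clusters with no direct member contribute
    nothing. Clusters whose direct members disagree propagate the union;
    such clusters are flagged in the report table.
    """
    direct_by_orf = {a.orf_id: a for a in direct_assignments}
    if len(direct_by_orf) != len(direct_assignments):
        raise ValueError("multiple direct assignments for one ORF")
    out: List[ECAssignment] = []
    for cluster in sorted(clusters, key=lambda c: c.cluster_id):
        members = sorted(cluster.members)
        direct_members = [direct_by_orf[m] for m in members if m in direct_by_orf]
        for m in members:
            if m in direct_by_orf:
                a = direct_by_orf[m]
                out.append(
                    ECAssignment(
                        orf_id=a.orf_id,
                        ec_numbers=a.ec_numbers,
                        provenance="rbh_direct",
                        best_hit_accession=a.best_hit_accession,
                        cluster_id=cluster.cluster_id,
                        function_names=a.function_names,
                    )
                )
        if not direct_members:
            continue
        ec_union = tuple(sorted({ec for a in direct_members for ec in a.ec_numbers}))
        name_union = tuple(
            sorted({n for a in direct_members for n in a.function_names})
        )
        for m in members:
            if m in direct_by_orf:
                continue
            out.append(
                ECAssignment(
                    orf_id=m,
                    ec_numbers=ec_union,
                    provenance="paralog_propagated",
                    cluster_id=cluster.cluster_id,
                    function_names=name_union,
                )
            )
    return out


def ambiguous_clusters(
    clusters: Sequence[ParalogCluster],
    direct_assignments: Sequence[ECAssignment],
) -> FrozenSet[int]:
    """Cluster ids whose direct members carry more than one distinct EC set."""
    direct_by_orf = {a.orf_id: a for a in direct_assignments}
    flagged = set()
    for cluster in clusters:
        ec_sets = {
            direct_by_orf[m].ec_numbers
            for m in cluster.members
            if m in direct_by_orf
        }
        if len(ec_sets) > 1:
            flagged.add(cluster.cluster_id)
    return frozenset(flagged)


def annotate_proteome(
    proteome: Sequence[SequenceRecord],
    enzyme_db: Sequence[EnzymeDbEntry],
    scheme: ScoringScheme,
    evalue_max: float = 1e-3,
    identity_min: float = 0.35,
    coverage_min: float = 0.70,
) -> Tuple[List[ECAssignment], List[ParalogCluster]]:
    """Full annotation stage: RBH transfer then paralog propagation."""
    pairs = reciprocal_best_hits(proteome, enzyme_db, scheme, evalue_max)
    direct = transfer_ec(pairs, enzyme_db)
    clusters = cluster_paralogs(
        proteome, scheme, identity_min=identity_min, coverage_min=coverage_min
    )
    return propagate_ec(clusters, direct), clusters


def assignments_table(
    assignments: Sequence[ECAssignment],
    clusters: Sequence[ParalogCluster] = (),
    direct_assignments: Sequence[ECAssignment] | None = None,
) -> pd.DataFrame:
    """Report table: one row per annotated ORF, ambiguous clusters flagged."""
    if direct_assignments is None:
        direct_assignments = [a for a in assignments if a.provenance == "rbh_direct"]
    flagged = ambiguous_clusters(clusters, direct_assignments) if clusters else frozenset()
    rows = [
        {
            "orf_id": a.orf_id,
            "ec_numbers": ";".join(a.ec_numbers),
            "function_names": ";".join(a.function_names),
            "provenance": a.provenance,
            "best_hit": a.best_hit_accession or "",
            "cluster_id": a.cluster_id if a.cluster_id is not None else -1,
            "ambiguous_cluster": a.cluster_id in flagged,
        }
        for a in sorted(assignments, key=lambda a: a.orf_id)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "ec_numbers",
            "function_names",
            "provenance",
            "best_hit",
            "cluster_id",
            "ambiguous_cluster",
        ],
    )
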
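"""Reciprocal-best-hit EC transfer and single-linkage paralog clustering."""

import numpy as np
import pytest

from orfpipe.align import evalue_for_score, length_coverage, local_align
from orfpipe.ec import (
    ECAssignment,
    EnzymeDbEntry,
    ambiguous_clusters,
    best_hits,
    cluster_paralogs,
    load_enzyme_db,
    propagate_ec,
    reciprocal_best_hits,
    transfer_ec,
)
from orfpipe.records import SequenceRecord, write_fasta
from orfpipe.synth import SimulationConfig, simulate_enzyme_db, simulate_proteome

from .conftest import AA20, mutate, random_protein
from .oracles import connected_components_dfs, mutual_best_bruteforce

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


def _entry(acc, residues, ecs=("1.1.1.1",)):
    return EnzymeDbEntry(acc, SequenceRecord(acc, residues, "protein"), tuple(ecs))


# ---------------------------------------------------------------------------
# best hits / RBH


def test_best_hit_identical_sequence_wins(prot_scheme, rng):
    target = random_protein(rng, 80)
    others = [
        SequenceRecord(f"t{i}", random_protein(rng, 80), "protein") for i in range(3)
    ]
    targets = [SequenceRecord("hit", target, "protein")] + others
    hits = best_hits([SequenceRecord("q", target, "protein")], targets, prot_scheme)
    assert hits["q"][0] == "hit"
    assert hits["q"][1].percent_identity == 1.0


def test_query_without_qualifying_hit_absent(prot_scheme, rng):
    q = SequenceRecord("q", random_protein(rng, 50), "protein")
    t = SequenceRecord("t", random_protein(rng, 50), "protein")
    hits = best_hits([q], [t], prot_scheme, evalue_max=1e-30)
    assert hits == {}
    with pytest.raises(ValueError, match="empty target"):
        best_hits([q], [], prot_scheme)


@pytest.mark.parametrize("trial", range(5))
def test_rbh_matches_mutual_argmax_bruteforce(prot_scheme, trial):
    """RBH set equals an independent mutual-argmax over the score table."""
    rng = np.random.default_rng(500 + trial)
    n_orf, n_db = int(rng.integers(4, 9)), int(rng.integers(3, 7))
    ancestors = [random_protein(rng, int(rng.integers(40, 90))) for _ in range(n_db)]
    db = [_entry(f"E{j}", ancestors[j], (f"1.1.1.{j+1}",)) for j in range(n_db)]
    proteome = []
    for i in range(n_orf):
        anc = ancestors[int(rng.integers(n_db))]
        proteome.append(
            SequenceRecord(f"o{i}", mutate(anc, 0.7, rng), "protein")
        )
    scores = {}
    for q in proteome:
        for e in db:
            aln = local_align(q, e.record, prot_scheme)
            scores[(q.id, e.record.id)] = (aln.score, aln.evalue)
            scores[(e.record.id, q.id)] = (
                aln.score,
                evalue_for_score(aln.score, len(e.record), len(q), prot_scheme),
            )
    expected = mutual_best_bruteforce(
        scores, [p.id for p in proteome], [e.record.id for e in db], 1e-3
    )
    assert reciprocal_best_hits(proteome, db, prot_scheme) == expected


def test_non_reciprocal_pair_excluded(prot_scheme, rng):
    # q's best is s, but s's best is q2 (an exact copy of s)
    anc = random_protein(rng, 80)
    q = SequenceRecord("q", mutate(anc, 0.8, rng), "protein")
    q2 = SequenceRecord("q2", anc, "protein")
    db = [_entry("s", anc)]
    pairs = reciprocal_best_hits([q, q2], db, prot_scheme)
    assert pairs == [("q2", "s")]


def test_identity_bijection_all_rbh(prot_scheme, rng):
    seqs = [random_protein(rng, 60) for _ in range(4)]
    proteome = [SequenceRecord(f"o{i}", s, "protein") for i, s in enumerate(seqs)]
    db = [_entry(f"E{i}", s, (f"2.2.2.{i+1}",)) for i, s in enumerate(seqs)]
    assert reciprocal_best_hits(proteome, db, prot_scheme) == [
        (f"o{i}", f"E{i}") for i in range(4)
    ]


def test_transfer_ec_carries_all_ecs():
    db = [_entry("P00001", "MKVLAWGKEV", ("1.1.1.1", "2.7.1.1"))]
    assignments = transfer_ec([("orf1", "P00001")], db)
    assert assignments == [
        ECAssignment("orf1", ("1.1.1.1", "2.7.1.1"), "rbh_direct", "P00001")
    ]


# ---------------------------------------------------------------------------
# clustering


def test_three_identical_sequences_one_cluster(prot_scheme, rng):
    s = random_protein(rng, 60)
    proteome = [SequenceRecord(f"p{i}", s, "protein") for i in range(3)]
    clusters = cluster_paralogs(proteome, prot_scheme)
    assert len(clusters) == 1 and clusters[0].members == {"p0", "p1", "p2"}


def test_single_linkage_chaining(prot_scheme):
    """a~b and b~c above threshold, a~c below: one cluster through b."""
    rng = np.random.default_rng(77)
    b = random_protein(rng, 120)
    a = mutate(b, 0.55, rng)
    c = mutate(b, 0.55, rng)
    ra, rb, rc = (
        SequenceRecord("a", a, "protein"),
        SequenceRecord("b", b, "protein"),
        SequenceRecord("c", c, "protein"),
    )
    aln_ac = local_align(ra, rc, prot_scheme)
    cov = min(
        length_coverage(aln_ac, ra, "query"), length_coverage(aln_ac, rc, "subject")
    )
    # the a-c pair itself fails the 35%/70% edge test...
    assert aln_ac.percent_identity < 0.35 or cov < 0.70
    # ...yet chaining through b yields a single cluster
    clusters = cluster_paralogs([ra, rb, rc], prot_scheme)
    assert len(clusters) == 1 and clusters[0].members == {"a", "b", "c"}


@pytest.mark.parametrize("trial", range(4))
def test_clusters_match_dfs_on_explicit_edge_graph(prot_scheme, trial):
    rng = np.random.default_rng(900 + trial)
    n_fam = int(rng.integers(2, 4))
    ancestors = [random_protein(rng, int(rng.integers(50, 90))) for _ in range(n_fam)]
    proteome = []
    for i in range(int(rng.integers(6, 11))):
        if rng.random() < 0.75:
            seq = mutate(ancestors[int(rng.integers(n_fam))], 0.75, rng)
        else:
            seq = random_protein(rng, int(rng.integers(50, 90)))
        proteome.append(SequenceRecord(f"p{i:02d}", seq, "protein"))
    edges = []
    for i, a in enumerate(proteome):
        for b in proteome[i + 1 :]:
            aln = local_align(a, b, prot_scheme)
            if aln.aln_length == 0 or aln.percent_identity < 0.35:
                continue
            if (
                length_coverage(aln, a, "query") >= 0.70
                and length_coverage(aln, b, "subject") >= 0.70
            ):
                edges.append((a.id, b.id))
    expected = set(connected_components_dfs([p.id for p in proteome], edges))
    got = {c.members for c in cluster_paralogs(proteome, prot_scheme)}
    assert got == expected


def test_clustering_partition_and_order_invariance(prot_scheme, rng):
    anc = random_protein(rng, 70)
    proteome = [
        SequenceRecord(f"p{i}", mutate(anc, 0.8, rng), "protein") for i in range(4)
    ] + [SequenceRecord("lone", random_protein(rng, 70), "protein")]
    clusters = cluster_paralogs(proteome, prot_scheme)
    all_members = [m for c in clusters for m in c.members]
    assert sorted(all_members) == sorted(p.id for p in proteome)  # partition
    shuffled = list(reversed(proteome))
    assert [c.members for c in cluster_paralogs(shuffled, prot_scheme)] == [
        c.members for c in clusters
    ]


# ---------------------------------------------------------------------------
# propagation


def _cluster(cid, members):
    from orfpipe.ec import ParalogCluster

    return ParalogCluster(cid, frozenset(members))


def test_propagation_union_and_no_directless_contribution():
    direct = [
        ECAssignment("a", ("1.1.1.1",), "rbh_direct", "E1"),
        ECAssignment("b", ("2.2.2.2",), "rbh_direct", "E2"),
    ]
    clusters = [_cluster(0, {"a", "b", "c"}), _cluster(1, {"d", "e"})]
    result = propagate_ec(clusters, direct)
    by_orf = {a.orf_id: a for a in result}
    assert by_orf["c"].ec_numbers == ("1.1.1.1", "2.2.2.2")
    assert by_orf["c"].provenance == "paralog_propagated"
    assert by_orf["a"].ec_numbers == ("1.1.1.1",)  # direct unchanged
    assert "d" not in by_orf and "e" not in by_orf
    assert len(result) >= len(direct)
    assert ambiguous_clusters(clusters, direct) == {0}


def test_simple_propagation():
    direct = [ECAssignment("a", ("1.1.1.1",), "rbh_direct", "E1")]
    result = propagate_ec([_cluster(0, {"a", "b"})], direct)
    by_orf = {a.orf_id: a for a in result}
    assert by_orf["b"].ec_numbers == ("1.1.1.1",)
    assert by_orf["b"].cluster_id == 0


# ---------------------------------------------------------------------------
# synthetic recovery and negative control (small versions)


def test_family_members_recover_ancestor_ec(prot_scheme):
    cfg = SimulationConfig(
        seed=11, n_families=4, members_per_family=3, n_decoys=4,
        ancestor_length_range=(120, 200),
    )
    db = simulate_enzyme_db(cfg)
    proteome, truth = simulate_proteome(db, cfg)
    pairs = reciprocal_best_hits(proteome, db, prot_scheme)
    direct = transfer_ec(pairs, db)
    assignments = propagate_ec(cluster_paralogs(proteome, prot_scheme), direct)
    annotated = {a.orf_id: a.ec_numbers for a in assignments}
    members = truth[~truth.is_decoy]
    recovered = sum(
        1 for r in members.itertuples() if r.true_ec in annotated.get(r.orf_id, ())
    )
    assert recovered / len(members) >= 0.95
    decoys = truth[truth.is_decoy]
    assert not any(r.orf_id in annotated for r in decoys.itertuples())


def test_load_enzyme_db_roundtrip(tmp_path, rng):
    entries = [
        _entry("A1", random_protein(rng, 40), ("1.2.3.4",)),
        EnzymeDbEntry(
            "A2",
            SequenceRecord("A2", random_protein(rng, 40), "protein"),
            (),
            source="aracyc_like",
            function_names=("putative synthase",),
        ),
    ]
    write_fasta([e.record for e in entries], tmp_path / "db.faa")
    (tmp_path / "db.tsv").write_text(
        "accession\tannotation\nA1\t1.2.3.4\nA2\tputative synthase\n"
    )
    loaded = load_enzyme_db(tmp_path / "db.faa", tmp_path / "db.tsv")
    assert loaded[0].ec_numbers == ("1.2.3.4",)
    assert loaded[1].ec_numbers == () and loaded[1].source == "aracyc_like"
    assert loaded[1].function_names == ("putative synthase",)


def test_malformed_ec_rejected(rng):
    with pytest.raises(ValueError, match="malformed EC"):
        _entry("X", random_protein(rng, 30), ("1.2.3",))
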
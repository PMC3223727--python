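"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — exhaustive enumeration and plain
Python sorts — kept separate from the library code paths they check.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple


def global_affine_score(x: str, y: str, score_fn, gap_open: int, gap_extend: int) -> float:
    """End-to-end affine alignment score of two (short) strings by
    exhaustive recursion over alignment paths."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(x) and j == len(y):
            return 0.0
        best = -math.inf
        if i < len(x) and j < len(y):
            best = max(best, score_fn(x[i], y[j]) + rec(i + 1, j + 1, "M"))
        if i < len(x):
            cost = gap_extend if prev == "X" else gap_open
            best = max(best, cost + rec(i + 1, j, "X"))
        if j < len(y):
            cost = gap_extend if prev == "Y" else gap_open
            best = max(best, cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "S")


def sw_bruteforce(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Optimal local score: max end-to-end score over all substring pairs
    (the empty alignment scores 0)."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for j1 in range(i1, len(a) + 1):
            for i2 in range(len(b) + 1):
                for j2 in range(i2, len(b) + 1):
                    best = max(
                        best,
                        global_affine_score(
                            a[i1:j1], b[i2:j2], score_fn, gap_open, gap_extend
                        ),
                    )
    return int(best)


def mutual_best_bruteforce(
    fwd_scores: Dict[Tuple[str, str], Tuple[int, float]],
    query_ids: Sequence[str],
    target_ids: Sequence[str],
    evalue_max: float,
) -> List[Tuple[str, str]]:
    """Reciprocal best pairs from a {(q, t): (score, evalue)} table.

    Best hit per side = highest score among pairs with evalue <= max,
    ties to the lexicographically smaller partner id.
    """

    def best_for(qid: str, candidates: Sequence[str], lookup) -> str | None:
        scored = [
            (lookup(qid, t)[0], t)
            for t in candidates
            if lookup(qid, t)[1] <= evalue_max
        ]
        if not scored:
            return None
        top_score = max(s for s, _ in scored)
        return min(t for s, t in scored if s == top_score)

    pairs = []
    for q in query_ids:
        t = best_for(q, target_ids, lambda a, b: fwd_scores[(a, b)])
        if t is None:
            continue
        back = best_for(t, query_ids, lambda a, b: fwd_scores[(b, a)])
        if back == q:
            pairs.append((q, t))
    return sorted(pairs)


def connected_components_dfs(
    nodes: Sequence[str], edges: Sequence[Tuple[str, str]]
) -> List[frozenset]:
    """Connected components by explicit depth-first search."""
    adj: Dict[str, set] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def knn_counts_bruteforce(
    query_feat: Sequence[float],
    references: Sequence[Tuple[str, Sequence[float], str]],
    k: int,
) -> Dict[str, int]:
    """Uniform k-NN label counts by a full sort of all distances,
    distance ties broken by reference id."""
    scored = sorted(
        (
            (
                math.sqrt(sum((q - r) ** 2 for q, r in zip(query_feat, feat))),
                rid,
                label,
            )
            for rid, feat, label in references
        ),
    )
    counts: Dict[str, int] = {}
    for _, _, label in scored[:k]:
        counts[label] = counts.get(label, 0) + 1
    return counts
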
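"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths (and where possible the
libraries) they check: edit distances come from a plain dynamic
programme, clustering from union-find over the full distance matrix,
chimera calls from full enumeration of parent pairs and breakpoints, and
rarefaction from exhaustive subsample enumeration.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def levenshtein(a: str, b: str) -> int:
    """Edit distance by the textbook dynamic programme (numpy rows)."""
    if len(a) < len(b):
        a, b = b, a
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a.encode(), start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (bb != ca)
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        # insertion needs a sequential pass
        for j in range(1, len(b) + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[-1])


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def threshold_components(seqs: list[str], d: int) -> list[set[int]]:
    """Connected components of the <=d edit-distance graph (brute force)."""
    uf = UnionFind(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if levenshtein(seqs[i], seqs[j]) <= d:
                uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(uf.find(i), set()).add(i)
    return list(groups.values())


def k80_closed_form(P: float, Q: float) -> float:
    return -0.5 * math.log((1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q))


def exhaustive_chimera_flags(
    seqs: list[str],
    abundances: list[int],
    min_div: float = 0.8,
    min_score: float = 0.28,
    abskew: float = 2.0,
    xn: float = 8.0,
    dn: float = 1.4,
    xa: float = 1.0,
    min_parent_div: float = 1.0,
    max_noise_edits: int = 5,
) -> list[bool]:
    """Chimera verdicts by full enumeration of (parent A, parent B, breakpoint).

    Mirrors the detection contract — identity gain over the best single
    parent, per-side weighted votes, minimum parent divergence, and the
    frame-shift guard — but computes every quantity by direct enumeration.
    """
    n = len(seqs)
    L = len(seqs[0])
    flags = [False] * n
    if n < 3:
        return flags
    for q in range(n):
        cands = [c for c in range(n) if c != q and abundances[c] >= abskew * abundances[q]]
        if len(cands) < 2:
            continue
        singles = {c: sum(x == y for x, y in zip(seqs[q], seqs[c])) for c in cands}
        best_single_c = max(cands, key=lambda c: singles[c])
        best_single = singles[best_single_c]

        best = (-1, None)
        for a, b in itertools.permutations(cands, 2):
            for bp in range(L + 1):
                m = sum(x == y for x, y in zip(seqs[q][:bp], seqs[a][:bp]))
                m += sum(x == y for x, y in zip(seqs[q][bp:], seqs[b][bp:]))
                if m > best[0]:
                    best = (m, (a, b, bp))
        if best[1] is None:
            continue
        m, (a, b, bp) = best
        div = (m - best_single) / L * 100.0
        if div < min_div:
            continue
        s_edit = levenshtein(seqs[q], seqs[best_single_c])
        if (L - best_single) > s_edit and s_edit <= max_noise_edits:
            continue
        if levenshtein(seqs[a], seqs[b]) / L * 100.0 < min_parent_div:
            continue

        def side_score(lo: int, hi: int, model: str, other: str) -> float:
            yes = no = abstain = 0
            for i in range(lo, hi):
                if seqs[a][i] == seqs[b][i]:
                    continue
                if seqs[q][i] == model[i] != other[i]:
                    yes += 1
                elif seqs[q][i] == other[i] != model[i]:
                    no += 1
                else:
                    abstain += 1
            denom = yes + xn * (no + dn / 2.0) + xa * abstain
            return yes / denom if denom > 0 else 0.0

        score = min(
            side_score(0, bp, seqs[a], seqs[b]),
            side_score(bp, L, seqs[b], seqs[a]),
        )
        flags[q] = score >= min_score
    return flags


def rarefaction_by_enumeration(counts: list[int], n: int) -> float:
    """Mean richness over every distinct subsample of size n (exhaustive)."""
    pool = [taxon for taxon, c in enumerate(counts) for _ in range(c)]
    total = 0.0
    m = 0
    for combo in itertools.combinations(range(len(pool)), n):
        total += len({pool[i] for i in combo})
        m += 1
    return total / m
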
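"""Single-linkage amplicon clustering at a local edit-distance threshold.

MOTUs are built the way SWARM v1 builds them: starting from the most
abundant unassigned amplicon, the cluster grows by breadth-first
exploration of the graph whose edges join amplicon pairs at most ``d``
differences apart (full Levenshtein distance — mismatches and indels both
count).  The result is exactly the set of connected components of that
graph; the iterative seeded growth only fixes the output order and the
seed (most abundant member) of each MOTU.  The default ``d = 2`` is the
local threshold used for foraminiferal rDNA, whose extreme substitution
rates rule out a single global clustering radius.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .chimera import Amplicon
from .readprep import Read


def seq_distance(a: str, b: str) -> int:
    """Number of differences between two DNA strings (Levenshtein distance)."""
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class MOTU:
    """A cluster of amplicons with per-sample abundances and a seed sequence."""

    id: str
    members: list[Amplicon]
    seed_sequence: str
    representative: str | None = None

    @property
    def total_reads(self) -> int:
        return sum(a.abundance for a in self.members)

    @property
    def sample_counts(self) -> dict[str, int]:
        counts: Counter = Counter()
        for a in self.members:
            counts.update(a.sample_counts)
        return dict(counts)

    @property
    def n_samples_present(self) -> int:
        return sum(1 for v in self.sample_counts.values() if v > 0)


def _neighbour_lists(seqs: Sequence[str], d: int) -> list[list[int]]:
    """All pairs at edit distance <= d (edlib with early-abandon at k=d)."""
    n = len(seqs)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        si = seqs[i]
        for j in range(i + 1, n):
            r = edlib.align(si, seqs[j], task="distance", k=d)
            if r["editDistance"] != -1:
                neigh[i].append(j)
                neigh[j].append(i)
    return neigh


def swarm_cluster(amplicons: Sequence[Amplicon], d: int = 2) -> list[MOTU]:
    """Cluster dereplicated amplicons into MOTUs at local threshold ``d``.

    Amplicons must be sorted by decreasing abundance (dereplicate order).
    Each MOTU is seeded at the most abundant unassigned amplicon and grown
    breadth-first over <= d-difference links; output follows seed
    abundance (desc, ties by sequence).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    amplicons = list(amplicons)
    order = sorted(
        range(len(amplicons)),
        key=lambda i: (-amplicons[i].abundance, amplicons[i].sequence),
    )
    seqs = [amplicons[i].sequence for i in order]
    neigh = _neighbour_lists(seqs, d)

    assigned = [False] * len(seqs)
    motus: list[MOTU] = []
    for seed in range(len(seqs)):
        if assigned[seed]:
            continue
        queue = [seed]
        assigned[seed] = True
        members: list[int] = []
        while queue:
            cur = queue.pop(0)
            members.append(cur)
            for nb in sorted(neigh[cur]):
                if not assigned[nb]:
                    assigned[nb] = True
                    queue.append(nb)
        motus.append(
            MOTU(
                id=f"motu{len(motus) + 1:05d}",
                members=[amplicons[order[i]] for i in sorted(members)],
                seed_sequence=seqs[seed],
            )
        )
    return motus


def abundance_occurrence_filter(
    motus: Iterable[MOTU], min_samples: int = 3, min_reads: int = 10
) -> tuple[list[MOTU], list[MOTU]]:
    """Split MOTUs into (retained, rare) by occurrence and total abundance.

    Retained MOTUs occur in at least ``min_samples`` samples and total at
    least ``min_reads`` reads; the rare remainder is kept for later
    meta-reference reassignment rather than discarded.
    """
    retained: list[MOTU] = []
    rare: list[MOTU] = []
    for m in motus:
        if m.n_samples_present >= min_samples and m.total_reads >= min_reads:
            retained.append(m)
        else:
            rare.append(m)
    return retained, rare


def select_representative(motu: MOTU, untrimmed_reads: Sequence[Read]) -> str:
    """Pick the MOTU's representative: the most abundant of the longest
    untrimmed reads whose sequence starts with the MOTU's seed.

    Trimming to 300 bp discards the 3' information needed for phylogenetic
    work, so the seed is used as a prefix key back into the pre-trim reads.
    Falls back to the seed itself when no longer read exists.
    """
    seed = motu.seed_sequence
    candidates: Counter = Counter()
    for read in untrimmed_reads:
        if read.sequence.startswith(seed) and len(read.sequence) > len(seed):
            candidates[read.sequence] += 1
    if not candidates:
        return seed
    max_len = max(len(s) for s in candidates)
    longest = {s: c for s, c in candidates.items() if len(s) == max_len}
    return min(longest, key=lambda s: (-longest[s], s))


def assign_representatives(
    motus: Iterable[MOTU], untrimmed_reads: Sequence[Read]
) -> None:
    """Set ``representative`` on each MOTU in place (prefix index once)."""
    by_prefix: dict[str, Counter] = defaultdict(Counter)
    motu_list = list(motus)
    if not motu_list:
        return
    seed_len = len(motu_list[0].seed_sequence)
    for read in untrimmed_reads:
        if len(read.sequence) > seed_len:
            by_prefix[read.sequence[:seed_len]][read.sequence] += 1
    for m in motu_list:
        candidates = by_prefix.get(m.seed_sequence)
        if not candidates:
            m.representative = m.seed_sequence
            continue
        max_len = max(len(s) for s in candidates)
        longest = {s: c for s, c in candidates.items() if len(s) == max_len}
        m.representative = min(longest, key=lambda s: (-longest[s], s))


def write_motu_table(motus: Iterable[MOTU], path, samples: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("motu_id\tamplicon_id\tabundance\t" + "\t".join(samples) + "\n")
        for m in motus:
            for a in m.members:
                row = [m.id, a.id, str(a.abundance)]
                row += [str(a.sample_counts.get(s, 0)) for s in samples]
                fh.write("\t".join(row) + "\n")
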
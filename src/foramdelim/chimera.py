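"""Dereplication and de-novo two-parent chimera screening.

PCR chimeras arise when an aborted extension product primes a different
template in a later cycle, producing a read whose left part matches one
biological sequence and whose right part matches another.  The detector
below follows the de-novo strategy popularised by UCHIME: each query is
modelled as the concatenation of two *more abundant* amplicons around a
single breakpoint, and flagged when the best such chimeric model explains
the query clearly better than any single parent does.

Scoring is a simplified per-column voting scheme.  At alignment columns
where the two putative parents disagree, the query casts a "yes" vote if
it matches the model parent for that side, a "no" vote if it matches the
other parent, and abstains otherwise; the score is

    h = Y / (Y + xn * (N + dn) + xa * A)

with the weights defaulting to the published UCHIME defaults
(xn=8, dn=1.4, xa=1).  A query is chimeric when the chimeric model's
identity exceeds the best single-parent identity by at least ``min_div``
percentage points and h >= ``min_score`` (defaults 0.8 and 0.28, the
USEARCH defaults).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from ._kmers import encode, kmer_profile, profile_matrix, shared_kmers
from .readprep import Read


@dataclass
class Amplicon:
    """A dereplicated unique sequence with per-sample abundances."""

    id: str
    sequence: str
    abundance: int
    sample_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ChimeraVerdict:
    query_id: str
    is_chimera: bool
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None
    score: float = 0.0
    divergence: float = 0.0  # identity gain of the chimeric model, % points


def dereplicate(reads: Iterable[Read]) -> list[Amplicon]:
    """Collapse identical sequences, keeping total and per-sample counts.

    Output is sorted by decreasing abundance, ties broken by
    lexicographically smaller sequence — the stable order that both the
    chimera search and clustering assume.  Requires equal-length reads.
    """
    totals: Counter = Counter()
    per_sample: dict[str, Counter] = defaultdict(Counter)
    lengths: set[int] = set()
    for read in reads:
        lengths.add(len(read.sequence))
        totals[read.sequence] += 1
        per_sample[read.sequence][read.sample_id or "sample"] += 1
    if len(lengths) > 1:
        raise ValueError(f"dereplicate requires equal-length reads, got lengths {sorted(lengths)}")
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Amplicon(
            id=f"amp{i:06d}",
            sequence=seq,
            abundance=count,
            sample_counts=dict(per_sample[seq]),
        )
        for i, (seq, count) in enumerate(ordered, start=1)
    ]


def detect_chimeras(
    amplicons: Sequence[Amplicon],
    min_div: float = 0.8,
    min_score: float = 0.28,
    abskew: float = 2.0,
    xn: float = 8.0,
    dn: float = 1.4,
    xa: float = 1.0,
    min_parent_div: float = 1.0,
    max_noise_edits: int = 5,
    top_k: int = 64,
    exhaustive_below: int = 200,
) -> list[ChimeraVerdict]:
    """Screen abundance-sorted amplicons for two-parent chimeras.

    Parents are restricted to amplicons at least ``abskew`` times more
    abundant than the query (chimeras cannot out-amplify their templates
    early on), and the two parents of an accepted model must themselves
    be at least ``min_parent_div`` percent divergent by edit distance —
    a pair of near-identical parents (e.g. a sequence and its own
    homopolymer-indel variant, positionally very different but one edit
    apart) cannot form a meaningful chimera.  Above ``exhaustive_below``
    amplicons the candidate-parent set is narrowed to the ``top_k`` most
    similar by shared 4-mers, ranked per query quarter.
    """
    n = len(amplicons)
    verdicts = [ChimeraVerdict(query_id=a.id, is_chimera=False) for a in amplicons]
    if n < 3:
        return verdicts

    seqs = [a.sequence for a in amplicons]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("detect_chimeras requires equal-length amplicons")
    mat = np.stack([encode(s) for s in seqs])
    abunds = np.array([a.abundance for a in amplicons])
    use_kmer_screen = n > exhaustive_below
    profiles = profile_matrix(seqs) if use_kmer_screen else None

    for q in range(n):
        cand = np.flatnonzero(abunds >= abskew * abunds[q])
        cand = cand[cand != q]
        if cand.size < 2:
            continue
        if use_kmer_screen and cand.size > top_k:
            # rank candidates per query quarter, not globally: a parent
            # contributing only a short 3' (or 5') segment would otherwise
            # be crowded out by whole-length near-matches of the other parent
            quarter = max(length // 4, 1)
            keep_idx: set[int] = set()
            per_chunk = max(top_k // 4, 1)
            for start in range(0, length, quarter):
                chunk_prof = kmer_profile(seqs[q][start : start + quarter])
                sim = shared_kmers(profiles[cand], chunk_prof)
                order_c = np.argsort(-sim, kind="stable")[:per_chunk]
                keep_idx.update(int(i) for i in order_c)
            cand = cand[np.sort(np.fromiter(keep_idx, dtype=int))]

        eq = mat[cand] == mat[q][None, :]  # (C, L)
        pref = np.zeros((cand.size, length + 1), dtype=np.int32)
        np.cumsum(eq, axis=1, out=pref[:, 1:])
        total = pref[:, -1]
        best_single = int(total.max())

        suf = total[:, None] - pref  # matches in [i, L)
        # best chimeric model: max over breakpoint i of pref[A,i] + suf[B,i], A != B
        order = np.argsort(-pref, axis=0, kind="stable")
        a1 = order[0]  # per-breakpoint best left parent
        b_best = np.argmax(suf, axis=0)
        same = a1 == b_best
        chim = pref[a1, np.arange(length + 1)] + suf[b_best, np.arange(length + 1)]
        if same.any() and cand.size > 1:
            a2 = order[1]
            suf_sorted = np.argsort(-suf, axis=0, kind="stable")
            b2 = suf_sorted[1]
            alt1 = pref[a2, np.arange(length + 1)] + suf[b_best, np.arange(length + 1)]
            alt2 = pref[a1, np.arange(length + 1)] + suf[b2, np.arange(length + 1)]
            chim = np.where(same, np.maximum(alt1, alt2), chim)
            use_alt1 = same & (alt1 >= alt2)
        else:
            use_alt1 = np.zeros(length + 1, dtype=bool)

        bp = int(np.argmax(chim))
        best_chim = int(chim[bp])
        div = (best_chim - best_single) / length * 100.0
        if div < min_div:
            continue

        # frame-shift guard: a query whose best single parent explains it
        # within sequencing noise by *edit* distance, but poorly position
        # by position (Hamming > edit), is an indel variant of that parent
        # — its shifted tail would otherwise be "explained" by an
        # arbitrary second parent sharing the shifted frame
        s_idx = int(np.argmax(total))
        s_edit = edlib.align(seqs[q], seqs[cand[s_idx]], task="distance")["editDistance"]
        s_hamming = length - int(total[s_idx])
        if s_hamming > s_edit and s_edit <= max_noise_edits:
            continue

        ia = int(order[1][bp]) if use_alt1[bp] else int(a1[bp])
        if same[bp] and not use_alt1[bp]:
            ib = int(np.argsort(-suf[:, bp], kind="stable")[1])
        else:
            ib = int(b_best[bp])
        parent_dist = edlib.align(
            seqs[cand[ia]], seqs[cand[ib]], task="distance"
        )["editDistance"]
        if parent_dist / length * 100.0 < min_parent_div:
            continue
        score = _vote_score(mat[q], mat[cand[ia]], mat[cand[ib]], bp, xn, dn, xa)
        if score < min_score:
            continue
        verdicts[q] = ChimeraVerdict(
            query_id=amplicons[q].id,
            is_chimera=True,
            parent_a=amplicons[cand[ia]].id,
            parent_b=amplicons[cand[ib]].id,
            breakpoint=bp,
            score=score,
            divergence=div,
        )
    return verdicts


def _vote_score(
    q: np.ndarray,
    pa: np.ndarray,
    pb: np.ndarray,
    bp: int,
    xn: float,
    dn: float,
    xa: float,
) -> float:
    """UCHIME-style h score of the model (pa[:bp] + pb[bp:]) for query q.

    Votes are tallied separately on each side of the breakpoint and the
    weaker side decides: a genuine two-parent chimera must be supported
    by diagnostic columns on *both* sides, whereas one-sided artifacts
    (e.g. a frame-shifted 3' tail drifting towards an arbitrary second
    parent) collect "no" votes against the model on the far side.  The
    ``dn`` pseudo-count is a prior on the model's total no votes, so each
    segment carries half of it.
    """
    diff = pa != pb
    left = np.arange(len(q)) < bp
    model = np.where(left, pa, pb)
    other = np.where(left, pb, pa)

    def _side(mask: np.ndarray) -> float:
        yes = int(np.sum(mask & diff & (q == model)))
        no = int(np.sum(mask & diff & (q == other)))
        abstain = int(np.sum(mask & diff)) - yes - no
        denom = yes + xn * (no + dn / 2.0) + xa * abstain
        return yes / denom if denom > 0 else 0.0

    return min(_side(left), _side(~left))


def remove_chimeras(
    amplicons: Sequence[Amplicon], verdicts: Sequence[ChimeraVerdict]
) -> tuple[list[Amplicon], list[Amplicon]]:
    """Split amplicons into (clean, flagged) according to the verdicts."""
    flagged_ids = {v.query_id for v in verdicts if v.is_chimera}
    clean = [a for a in amplicons if a.id not in flagged_ids]
    flagged = [a for a in amplicons if a.id in flagged_ids]
    return clean, flagged


def write_verdicts(verdicts: Iterable[ChimeraVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tis_chimera\tparent_a\tparent_b\tbreakpoint\tscore\tdivergence\n")
        for v in verdicts:
            fh.write(
                f"{v.query_id}\t{'Y' if v.is_chimera else 'N'}\t"
                f"{v.parent_a or ''}\t{v.parent_b or ''}\t"
                f"{'' if v.breakpoint is None else v.breakpoint}\t"
                f"{v.score:.4f}\t{v.divergence:.2f}\n"
            )
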
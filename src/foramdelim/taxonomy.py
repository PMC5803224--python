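"""Reference-database assignment and meta-reference reassignment.

MOTU seeds are compared to annotated references by global-global
(Needleman-Wunsch) alignment, ggsearch-style: percent identity is
matches over all alignment columns, end gaps included.  The module also
builds the *meta-reference* — curated planktonic and benthic references
plus the delineated environmental representatives — and reassigns the
complete MOTU set (abundant and rare) against it, retaining MOTUs above
the identity threshold with unambiguous attribution and merging MOTUs
that share a taxonomic path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from ._kmers import profile_matrix, kmer_profile, shared_kmers
from .clustering import MOTU
from .taxon import ReferenceSeq, TaxonPath

AMBIGUITY_EPS = 1e-9


def _make_aligner(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -12.0,
    gap_extend: float = -4.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def global_identity(query: str, ref: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity of the best global-global alignment.

    Identity = matches / alignment columns x 100, counting every column
    including terminal gaps (global semantics, as in ggsearch).
    """
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    if query == ref:
        return 100.0
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(query, ref)[0]
    counts = aln.counts()
    columns = aln.shape[1]
    return counts.identities / columns * 100.0


def _identity(query: str, ref: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity with an ungapped fast path.

    When both sequences have equal length and the Levenshtein-optimal
    alignment needs no indels (edit distance equals the Hamming
    distance), the ungapped alignment is also optimal under the heavy
    default gap penalties and identity is (L - d) / L; otherwise fall
    back to the full global aligner.
    """
    if len(query) == len(ref):
        if query == ref:
            return 100.0
        d = edlib.align(query, ref, task="distance")["editDistance"]
        h = sum(a != b for a, b in zip(query, ref))
        if d == h:
            return (len(query) - d) / len(query) * 100.0
    return global_identity(query, ref, aligner)


@dataclass
class Assignment:
    query_id: str
    best_hit_id: str | None
    identity: float
    path: tuple[str, ...]
    ambiguous: bool = False


def assign(
    query_id: str,
    query_seq: str,
    refdb: Sequence[ReferenceSeq],
    prescreen_k: int | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> Assignment:
    """Best-hit assignment of one query against a reference database.

    Ties at equal identity are unambiguous when every best hit agrees at
    the morphospecies rank; hits agreeing at morphospecies but differing
    at genetic type assign to that morphospecies with genetic type
    "unresolved"; conflicts at morphospecies set ``ambiguous``.

    ``prescreen_k`` optionally restricts alignment to the k references
    sharing the most 4-mers with the query (exact best hit is then only
    guaranteed if the true best hit survives the prescreen).
    """
    if not refdb:
        raise ValueError("empty reference database")
    refs = list(refdb)
    if prescreen_k is not None and len(refs) > prescreen_k:
        profiles = profile_matrix([r.sequence for r in refs])
        sim = shared_kmers(profiles, kmer_profile(query_seq))
        keep = np.argsort(-sim, kind="stable")[:prescreen_k]
        refs = [refs[i] for i in sorted(keep)]

    identities = [_identity(query_seq, r.sequence, aligner) for r in refs]
    best = max(identities)
    hits = [r for r, ident in zip(refs, identities) if ident >= best - AMBIGUITY_EPS]
    best_hit = hits[0]
    if len(hits) == 1:
        return Assignment(query_id, best_hit.id, best, best_hit.path)

    taxa = [h.taxon for h in hits]
    morphospecies = {t.morphospecies for t in taxa}
    if len(morphospecies) > 1:
        return Assignment(query_id, best_hit.id, best, best_hit.path, ambiguous=True)
    genetic_types = {t.genetic_type for t in taxa}
    if len(genetic_types) > 1:
        path = best_hit.path[:-1] + ("unresolved",)
        return Assignment(query_id, best_hit.id, best, path)
    return Assignment(query_id, best_hit.id, best, best_hit.path)


def assign_motus(
    motus: Sequence[MOTU],
    refdb: Sequence[ReferenceSeq],
    prescreen_k: int | None = 20,
    aligner: Align.PairwiseAligner | None = None,
) -> dict[str, Assignment]:
    return {
        m.id: assign(m.id, m.seed_sequence, refdb, prescreen_k, aligner) for m in motus
    }


def screen_nonforam(
    motus: Sequence[MOTU], assignments: Mapping[str, Assignment], refdb: Sequence[ReferenceSeq]
) -> tuple[list[MOTU], list[MOTU]]:
    """Discard MOTUs whose best hit is not foraminiferan (PR2 path level 3)."""
    by_id = {r.id: r for r in refdb}
    foram: list[MOTU] = []
    discarded: list[MOTU] = []
    for m in motus:
        a = assignments[m.id]
        hit = by_id.get(a.best_hit_id)
        if hit is not None and hit.is_foraminifera:
            foram.append(m)
        else:
            discarded.append(m)
    return foram, discarded


@dataclass
class MetaReference:
    refs: list[ReferenceSeq]
    n_unique_paths: int
    warnings: list[str] = field(default_factory=list)


def build_meta_reference(
    pfr2like: Sequence[ReferenceSeq],
    pr2_benthics: Sequence[ReferenceSeq],
    motu_reps: Sequence[ReferenceSeq],
) -> MetaReference:
    """Merge curated references with delineated environmental representatives.

    Every entry must already carry a harmonised path whose last four
    ranks form the 4-rank nomenclature.  Entries sharing a path are kept;
    a warning is recorded when same-path sequences are mutually <95%
    identical (possible annotation conflict), but both are retained.
    """
    merged: list[ReferenceSeq] = []
    seen_ids: set[str] = set()
    for group, source in (
        (pfr2like, "reference-db"),
        (pr2_benthics, "reference-db"),
        (motu_reps, "environmental"),
    ):
        for r in group:
            if r.id in seen_ids:
                raise ValueError(f"duplicate sequence id {r.id!r} in meta-reference")
            seen_ids.add(r.id)
            merged.append(
                ReferenceSeq(id=r.id, sequence=r.sequence, path=r.path, source=source)
            )
    warnings_list: list[str] = []
    by_path: dict[tuple[str, ...], list[ReferenceSeq]] = {}
    for r in merged:
        by_path.setdefault(r.taxon.as_string(), []).append(r)  # type: ignore[arg-type]
    for path, rs in by_path.items():
        if len(rs) > 1:
            ident = global_identity(rs[0].sequence[:300], rs[1].sequence[:300])
            if ident < 95.0:
                warnings_list.append(
                    f"path {path} carried by sequences <95% identical ({rs[0].id}, {rs[1].id})"
                )
    return MetaReference(refs=merged, n_unique_paths=len(by_path), warnings=warnings_list)


@dataclass
class EcologicalDataset:
    """Final merged taxon x sample counts plus the exclusion report."""

    taxa: list[TaxonPath]
    counts: dict[TaxonPath, dict[str, int]]
    retained_motus: list[str]
    excluded_motus: list[tuple[str, str]]  # (motu_id, reason)
    excluded_reads: int = 0

    @property
    def total_reads(self) -> int:
        return sum(sum(v.values()) for v in self.counts.values())


def reassign_all(
    all_motus: Sequence[MOTU],
    meta: MetaReference,
    threshold: float = 95.0,
    inclusive: bool = False,
    prescreen_k: int | None = 20,
    trim_to: int | None = 300,
) -> EcologicalDataset:
    """Reassign every MOTU (abundant and rare) against the meta-reference.

    MOTUs with identity strictly greater than ``threshold`` (or >= with
    ``inclusive``) and unambiguous attribution inherit the hit's 4-rank
    path; MOTUs sharing a path are merged by summing abundance vectors.
    """
    refs = meta.refs
    if trim_to is not None:
        refs = [
            ReferenceSeq(id=r.id, sequence=r.sequence[:trim_to], path=r.path, source=r.source)
            for r in refs
        ]
    counts: dict[TaxonPath, dict[str, int]] = {}
    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    excluded_reads = 0
    for m in all_motus:
        a = assign(m.id, m.seed_sequence, refs, prescreen_k)
        ok = a.identity >= threshold if inclusive else a.identity > threshold
        if not ok:
            excluded.append((m.id, f"identity {a.identity:.2f} <= {threshold}"))
            excluded_reads += m.total_reads
            continue
        if a.ambiguous:
            excluded.append((m.id, "ambiguous attribution"))
            excluded_reads += m.total_reads
            continue
        taxon = TaxonPath.from_full_path(a.path)
        row = counts.setdefault(taxon, {})
        for sample, c in m.sample_counts.items():
            row[sample] = row.get(sample, 0) + c
        retained.append(m.id)
    return EcologicalDataset(
        taxa=sorted(counts),
        counts=counts,
        retained_motus=retained,
        excluded_motus=excluded,
        excluded_reads=excluded_reads,
    )
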
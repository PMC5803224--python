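"""Demultiplexing, primer filtering and trimming of tagged amplicon reads.

Raw 454-style reads carry an 8-nt sample tag followed by the forward
primer and the amplified rDNA fragment; a minority of reads are long
enough to run into the (reverse-complemented) reverse primer.  This
module assigns reads to samples, enforces the retention rules used for
the foraminiferal survey — exact forward primer, no ambiguous
nucleotides — and trims retained reads to a fixed 300 bp window after
the forward primer so that downstream clustering compares homologous
regions of equal length.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_FORWARD = "GTGCATGGCCGTTCTTAGTTC"  # S15rF
DEFAULT_REVERSE = "GTACRAGGCATTCCTRGTT"  # S19F (degenerate R positions)
DEFAULT_TRIM = 300

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

ACGT = frozenset("ACGT")


@dataclass
class PrimerSet:
    """Forward/reverse amplification primers plus the sample-tag length."""

    forward: str = DEFAULT_FORWARD
    reverse: str = DEFAULT_REVERSE
    tag_length: int = 8

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for p in (self.forward, self.reverse):
            if not p or any(c not in IUPAC for c in p):
                raise ValueError(f"primer is not uppercase IUPAC DNA: {p!r}")

    @property
    def reverse_rc(self) -> str:
        return str(Seq(self.reverse).reverse_complement())


@dataclass
class Read:
    """A sequencing read, optionally assigned to a sample."""

    id: str
    sequence: str
    sample_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleInfo:
    sample_id: str
    tag: str
    station: str = ""
    depth: str = ""
    size_fraction: str = ""


def load_tag_map(path: str | Path) -> dict[str, SampleInfo]:
    """Read the sample↔tag TSV (sample_id, tag, station, depth, size_fraction)."""
    out: dict[str, SampleInfo] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["sample_id"]] = SampleInfo(
                sample_id=row["sample_id"],
                tag=row["tag"].upper(),
                station=row.get("station", ""),
                depth=row.get("depth", ""),
                size_fraction=row.get("size_fraction", ""),
            )
    return out


def read_fasta(path: str | Path) -> Iterator[Read]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield Read(id=rec.id, sequence=str(rec.seq).upper())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[Read],
    tag_map: dict[str, SampleInfo],
    tolerance: int = 0,
) -> tuple[list[Read], list[tuple[Read, str]]]:
    """Assign each read to the sample whose tag starts the read.

    The tag occupies the first ``tag_length`` bases; up to ``tolerance``
    mismatches are allowed provided the best-matching tag is unique.
    Returns (assigned reads with the tag stripped, rejects with reason).
    Raises on duplicate tags in the map.
    """
    tags: dict[str, str] = {}
    for info in tag_map.values():
        if info.tag in tags:
            raise ValueError(f"duplicate tag {info.tag!r} in tag map")
        tags[info.tag] = info.sample_id
    tag_len = len(next(iter(tags)))

    assigned: list[Read] = []
    rejected: list[tuple[Read, str]] = []
    for read in reads:
        prefix = read.sequence[:tag_len]
        if len(prefix) < tag_len:
            rejected.append((read, "too_short"))
            continue
        if tolerance == 0:
            sample = tags.get(prefix)
            if sample is None:
                rejected.append((read, "no_tag_match"))
                continue
        else:
            dists = {t: _hamming(prefix, t) for t in tags}
            best = min(dists.values())
            hits = [t for t, d in dists.items() if d == best]
            if best > tolerance:
                rejected.append((read, "no_tag_match"))
                continue
            if len(hits) > 1:
                rejected.append((read, "ambiguous_tag"))
                continue
            sample = tags[hits[0]]
        assigned.append(
            Read(id=read.id, sequence=read.sequence[tag_len:], sample_id=sample)
        )
    return assigned, rejected


def quality_filter(
    reads: Iterable[Read], primers: PrimerSet
) -> tuple[list[Read], Counter]:
    """Retain reads starting with the exact forward primer and containing
    no ambiguous nucleotide; everything else is counted by rejection reason."""
    retained: list[Read] = []
    report: Counter = Counter()
    fwd = primers.forward
    for read in reads:
        if not read.sequence.startswith(fwd):
            report["primer_mismatch"] += 1
            continue
        if not ACGT.issuperset(read.sequence):
            report["ambiguous_base"] += 1
            continue
        retained.append(read)
        report["retained"] += 1
    return retained, report


def trim_after_primer(
    read: Read, primers: PrimerSet, length: int = DEFAULT_TRIM
) -> Read | None:
    """Return the ``length`` bp immediately 3' of the forward primer.

    Reads with fewer than ``length`` bases after the primer are dropped
    (returns None).  Already-trimmed reads (no primer, length <= trim
    length) pass through unchanged, making the operation idempotent.
    """
    seq = read.sequence
    if seq.startswith(primers.forward):
        rest = seq[len(primers.forward):]
        if len(rest) < length:
            return None
        return Read(id=read.id, sequence=rest[:length], sample_id=read.sample_id)
    if len(seq) <= length:
        return read
    raise ValueError(f"forward primer absent from read {read.id!r}")


def _iupac_match(window: str, pattern: str, max_mismatch: int) -> bool:
    mm = 0
    for w, p in zip(window, pattern):
        if w not in IUPAC.get(p, ()):
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def has_reverse_primer(read: Read, primers: PrimerSet, max_mismatch: int = 1) -> bool:
    """Search the 3' half of the read for the reverse-complemented reverse
    primer (IUPAC-aware, up to ``max_mismatch`` mismatches)."""
    target = primers.reverse_rc
    seq = read.sequence
    start = len(seq) // 2
    for i in range(max(start, 0), len(seq) - len(target) + 1):
        if _iupac_match(seq[i : i + len(target)], target, max_mismatch):
            return True
    return False


def reverse_primer_fraction(
    reads: Sequence[Read], primers: PrimerSet, max_mismatch: int = 1
) -> float:
    """Fraction of reads long enough to contain the reverse primer."""
    reads = list(reads)
    if not reads:
        return 0.0
    n_hit = sum(has_reverse_primer(r, primers, max_mismatch) for r in reads)
    return n_hit / len(reads)


@dataclass
class PrepResult:
    """Outcome of the full read-preparation stage."""

    trimmed: list[Read]
    untrimmed_retained: list[Read]  # primer-stripped, full remaining length
    reverse_primer_fraction: float
    report: Counter = field(default_factory=Counter)
    rejects: list[tuple[Read, str]] = field(default_factory=list)


def prep_reads(
    reads: Iterable[Read],
    tag_map: dict[str, SampleInfo],
    primers: PrimerSet | None = None,
    trim_length: int = DEFAULT_TRIM,
    tag_tolerance: int = 0,
) -> PrepResult:
    """Demultiplex, primer/ambiguity filter, and trim in one pass.

    ``untrimmed_retained`` keeps the full primer-stripped sequences of the
    retained reads: MOTU representative selection later searches these for
    the longest reads extending a MOTU's trimmed seed.
    """
    primers = primers or PrimerSet()
    assigned, rejects = demultiplex(reads, tag_map, tolerance=tag_tolerance)
    report = Counter({"input": len(assigned) + len(rejects)})
    for _, reason in rejects:
        report[f"demux_{reason}"] += 1
    retained, qreport = quality_filter(assigned, primers)
    report.update({f"filter_{k}": v for k, v in qreport.items() if k != "retained"})
    rp_fraction = reverse_primer_fraction(retained, primers)

    trimmed: list[Read] = []
    untrimmed: list[Read] = []
    for read in retained:
        t = trim_after_primer(read, primers, trim_length)
        if t is None:
            report["trim_too_short"] += 1
            continue
        trimmed.append(t)
        untrimmed.append(
            Read(
                id=read.id,
                sequence=read.sequence[len(primers.forward):],
                sample_id=read.sample_id,
            )
        )
    report["retained"] = len(trimmed)
    return PrepResult(
        trimmed=trimmed,
        untrimmed_retained=untrimmed,
        reverse_primer_fraction=rp_fraction,
        report=report,
        rejects=rejects,
    )
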
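"""Taxonomic paths and reference-database I/O.

The package uses a 4-rank molecular nomenclature for foraminifera —
``Morphogroup | Genus | Morphospecies | GeneticType`` — harmonised between
curated reference databases (PR2/PFR2-style annotated FASTA) and
environmental MOTUs.  Reference FASTA headers follow the PR2 dialect::

    >seqID taxonomy=Eukaryota;Rhizaria;Foraminifera;Globothalamea;Genus;Species;Type

The third rank (1-based level 3) of the full path decides whether a
sequence is foraminiferan.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

FORAM_RANK_LEVEL = 3  # 1-based level of "Foraminifera" in PR2-style paths
FORAM_NAME = "Foraminifera"


@dataclass(frozen=True, order=True)
class TaxonPath:
    """A 4-rank nomenclature entry: Morphogroup|Genus|Morphospecies|GeneticType."""

    morphogroup: str
    genus: str
    morphospecies: str
    genetic_type: str

    def as_string(self, sep: str = "|") -> str:
        return sep.join(
            (self.morphogroup, self.genus, self.morphospecies, self.genetic_type)
        )

    @classmethod
    def from_string(cls, s: str, sep: str = "|") -> "TaxonPath":
        parts = s.split(sep)
        if len(parts) != 4:
            raise ValueError(f"expected 4 ranks separated by {sep!r}, got {s!r}")
        return cls(*parts)

    @classmethod
    def from_full_path(cls, ranks: Sequence[str]) -> "TaxonPath":
        """Map a semicolon-style full path onto the 4-rank nomenclature.

        By convention the last four ranks of the full path carry
        morphogroup, genus, morphospecies and genetic type.
        """
        if len(ranks) < 4:
            raise ValueError(f"path too short to map to 4 ranks: {ranks!r}")
        return cls(*ranks[-4:])


@dataclass
class ReferenceSeq:
    """An annotated reference sequence (database entry or environmental rep)."""

    id: str
    sequence: str
    path: tuple[str, ...]  # full semicolon-delimited taxonomy, split
    source: str = "reference-db"  # "reference-db" | "environmental"

    @property
    def taxon(self) -> TaxonPath:
        return TaxonPath.from_full_path(self.path)

    @property
    def is_foraminifera(self) -> bool:
        return (
            len(self.path) >= FORAM_RANK_LEVEL
            and self.path[FORAM_RANK_LEVEL - 1] == FORAM_NAME
        )


def read_reference_fasta(path: str | Path) -> list[ReferenceSeq]:
    """Read a PR2-style annotated FASTA (``>id taxonomy=R1;R2;...``)."""
    refs: list[ReferenceSeq] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    refs.append(_parse_ref(header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        refs.append(_parse_ref(header, "".join(chunks)))
    return refs


def _parse_ref(header: str, seq: str) -> ReferenceSeq:
    fields = header.split(None, 1)
    seq_id = fields[0]
    path: tuple[str, ...] = ()
    if len(fields) > 1:
        for token in fields[1].split():
            if token.startswith("taxonomy="):
                path = tuple(token[len("taxonomy="):].split(";"))
    return ReferenceSeq(id=seq_id, sequence=seq.upper(), path=path)


def write_reference_fasta(refs: Iterable[ReferenceSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id} taxonomy={';'.join(ref.path)}\n")
            for i in range(0, len(ref.sequence), 80):
                fh.write(ref.sequence[i : i + 80] + "\n")


def load_rank_mapping(path: str | Path) -> dict[tuple[str, ...], TaxonPath]:
    """Load a TSV aligning source taxonomy paths onto the 4-rank nomenclature.

    Columns: source_path (semicolon-delimited), morphogroup, genus,
    morphospecies, genetic_type.
    """
    mapping: dict[tuple[str, ...], TaxonPath] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = tuple(row["source_path"].split(";"))
            mapping[key] = TaxonPath(
                row["morphogroup"],
                row["genus"],
                row["morphospecies"],
                row["genetic_type"],
            )
    return mapping
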
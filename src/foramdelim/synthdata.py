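"""Synthetic multiplexed amplicon communities with known ground truth.

The generator emulates the structure of a 454 metabarcoding survey of
planktonic foraminifera: samples from a station x depth (surface / deep
chlorophyll maximum) x plankton-size-fraction design, reads carrying an
8-nt sample tag and the forward primer, amplicons 350-700 bp of which
only a minority reach the reverse primer, PCR chimeras, pyrosequencing
errors (uniform substitutions plus homopolymer indels), and a hierarchy
of lineages — morphogroup > genus > morphospecies > genetic type — with
tiered divergences producing a barcode gap, including "long branch"
morphogroups with multiplied substitution rates.

Sequence evolution uses the Kimura 1980 (K80) substitution model, the
same model the delimitation stage assumes, so configured divergences are
expected K80 distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .readprep import DEFAULT_FORWARD, DEFAULT_REVERSE, IUPAC, PrimerSet, Read, SampleInfo
from .taxon import ReferenceSeq, TaxonPath

_BASES = np.array([0, 1, 2, 3], dtype=np.uint8)  # A, G, C, T (purines first)
_ALPHABET = np.frombuffer(b"AGCT", dtype=np.uint8)
_TRANSITION = {0: 1, 1: 0, 2: 3, 3: 2}

MORPHOGROUP_POOL = [
    "Spinose",
    "Non-Spinose",
    "Microperforate",
    "Basal",
    "Long-Branch-I",
    "Long-Branch-II",
]


@dataclass
class TruthTaxonomy:
    """The generating taxonomy: unique 4-rank paths plus per-morphogroup rates."""

    paths: list[TaxonPath]
    rate_multiplier: dict[str, float]

    @property
    def morphogroups(self) -> list[str]:
        seen: list[str] = []
        for p in self.paths:
            if p.morphogroup not in seen:
                seen.append(p.morphogroup)
        return seen

    def __post_init__(self) -> None:
        if len(set(self.paths)) != len(self.paths):
            raise ValueError("taxonomy paths must be unique")
        if any(m < 1 for m in self.rate_multiplier.values()):
            raise ValueError("rate multipliers must be >= 1")


def generate_taxonomy(
    n_morphogroups: int = 4,
    genera_per_morphogroup: int = 1,
    species_per_genus: int = 2,
    types_per_species: int = 2,
    rate_multipliers: Mapping[str, float] | None = None,
    seed: int = 0,
) -> TruthTaxonomy:
    """Build a nested 4-rank taxonomy with the given counts per rank.

    Deterministic for a fixed seed (the seed only shuffles nothing here
    but is kept in the signature for forward compatibility of configs).
    Morphogroup names come from the canonical clade pool; "Long-Branch"
    groups default to a 3x substitution-rate multiplier.
    """
    for name, v in (
        ("n_morphogroups", n_morphogroups),
        ("genera_per_morphogroup", genera_per_morphogroup),
        ("species_per_genus", species_per_genus),
        ("types_per_species", types_per_species),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    names = [
        MORPHOGROUP_POOL[i] if i < len(MORPHOGROUP_POOL) else f"Morphogroup{i + 1}"
        for i in range(n_morphogroups)
    ]
    paths: list[TaxonPath] = []
    for gi, group in enumerate(names):
        for ge in range(genera_per_morphogroup):
            genus = f"{group}_G{ge + 1}"
            for sp in range(species_per_genus):
                species = f"{genus}_sp{sp + 1}"
                for ty in range(types_per_species):
                    paths.append(TaxonPath(group, genus, species, f"Type{ty + 1}"))
    rates = {g: 3.0 if g.startswith("Long-Branch") else 1.0 for g in names}
    if rate_multipliers:
        rates.update(rate_multipliers)
    return TruthTaxonomy(paths=paths, rate_multiplier=rates)


# ---------------------------------------------------------------------------
# K80 sequence evolution


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-transversion prob) after branch length t
    expected substitutions/site under K80 with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return float(p_ts), float(p_tv)


def evolve_sequence(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence along a branch of length t (K80)."""
    if t <= 0:
        return codes.copy()
    p_ts, p_tv = _k80_probs(t, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    trans = np.array([1, 0, 3, 2], dtype=np.uint8)
    out[ts_mask] = trans[codes[ts_mask]]
    # transversion targets: the two bases of the other chemical class
    tv_a = np.array([2, 2, 0, 0], dtype=np.uint8)
    tv_b = np.array([3, 3, 1, 1], dtype=np.uint8)
    out[tv1_mask] = tv_a[codes[tv1_mask]]
    out[tv2_mask] = tv_b[codes[tv2_mask]]
    return out


def decode(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode()


def encode_dna(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.uint8)
    out[arr == ord("G")] = 1
    out[arr == ord("C")] = 2
    out[arr == ord("T")] = 3
    return out


def evolve_references(
    taxonomy: TruthTaxonomy,
    root_length: int = 650,
    divergence_between_types: float = 0.05,
    divergence_between_species: float = 0.15,
    divergence_between_groups: float = 0.30,
    kappa: float = 2.0,
    seed: int = 0,
) -> list[ReferenceSeq]:
    """One reference sequence per genetic type, evolved down the hierarchy.

    K80 distances are additive in expectation, so branch lengths are set
    top-down such that the *expected pairwise* distance between two
    genetic types of one morphospecies is ``divergence_between_types``
    and between two morphospecies of one genus
    ``divergence_between_species`` (the deeper branches subtract the
    divergence already contributed by shallower ones).  Genera within a
    morphogroup sit at ~1.5x the species divergence, morphogroups at
    least ``divergence_between_groups`` apart.  A morphogroup's rate
    multiplier scales every branch inside it.
    """
    if root_length < 350:
        raise ValueError("root_length must be >= 350 bp")
    if not divergence_between_types < divergence_between_species:
        raise ValueError("divergence ordering violated: types must diverge less than species")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=root_length).astype(np.uint8)

    refs: list[ReferenceSeq] = []
    by_group: dict[str, list[TaxonPath]] = {}
    for p in taxonomy.paths:
        by_group.setdefault(p.morphogroup, []).append(p)

    for group, paths in by_group.items():
        m = taxonomy.rate_multiplier.get(group, 1.0)
        group_anc = evolve_sequence(root, m * divergence_between_groups / 2, kappa, rng)
        by_genus: dict[str, list[TaxonPath]] = {}
        for p in paths:
            by_genus.setdefault(p.genus, []).append(p)
        for genus, gpaths in by_genus.items():
            genus_anc = evolve_sequence(
                group_anc, m * divergence_between_species / 4, kappa, rng
            )
            by_species: dict[str, list[TaxonPath]] = {}
            for p in gpaths:
                by_species.setdefault(p.morphospecies, []).append(p)
            for species, spaths in by_species.items():
                species_anc = evolve_sequence(
                    genus_anc,
                    m * (divergence_between_species - divergence_between_types) / 2,
                    kappa,
                    rng,
                )
                for p in spaths:
                    tip = evolve_sequence(
                        species_anc, m * divergence_between_types / 2, kappa, rng
                    )
                    refs.append(
                        ReferenceSeq(
                            id=f"ref_{p.as_string('|').replace(' ', '_').replace('|', '.')}",
                            sequence=decode(tip),
                            path=(
                                "Eukaryota",
                                "Rhizaria",
                                "Foraminifera",
                                p.morphogroup,
                                p.genus,
                                p.morphospecies,
                                p.genetic_type,
                            ),
                        )
                    )
    return refs


def make_outgroup_references(
    n: int = 3, length: int = 650, seed: int = 1
) -> list[ReferenceSeq]:
    """Random non-foraminiferan references (diatom-style paths) for the
    screening stage."""
    rng = np.random.default_rng(seed)
    refs = []
    for i in range(n):
        seq = decode(rng.integers(0, 4, size=length).astype(np.uint8))
        refs.append(
            ReferenceSeq(
                id=f"outgroup{i + 1}",
                sequence=seq,
                path=(
                    "Eukaryota",
                    "Stramenopiles",
                    "Bacillariophyta",
                    "Diatomea",
                    f"DiatomGenus{i + 1}",
                    f"Diatom_sp{i + 1}",
                    "TypeX",
                ),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# Tag design


def generate_tags(
    n: int,
    length: int = 8,
    min_distance: int = 2,
    max_run: int = 2,
    seed: int = 0,
    max_tries: int = 100000,
) -> list[str]:
    """Sample-tag design by rejection: pairwise Hamming distance >= 2 and
    no more than ``max_run`` consecutive identical nucleotides."""
    rng = np.random.default_rng(seed)
    tags: list[str] = []
    alphabet = "ACGT"
    for _ in range(max_tries):
        if len(tags) >= n:
            break
        cand = "".join(alphabet[i] for i in rng.integers(0, 4, size=length))
        if any(
            all(cand[i] == cand[i + j] for j in range(1, max_run + 1))
            for i in range(length - max_run)
        ):
            continue
        if all(sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags):
            tags.append(cand)
    if len(tags) < n:
        raise RuntimeError(f"could not design {n} tags in {max_tries} tries")
    return tags


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey; defaults emulate the study design."""

    n_stations: int = 8
    depths: tuple[str, ...] = ("SUR", "DCM")
    size_fractions: tuple[str, ...] = ("20-180", "180-2000", ">0.8")
    reads_per_sample: int = 5000
    error_rate_sub: float = 0.003
    homopolymer_indel_rate: float = 0.0015
    ambiguous_rate: float = 0.0005
    chimera_fraction: float = 0.05
    nonforam_fraction: float = 0.10
    divergence_within_type: float = 0.002
    divergence_between_types: float = 0.05
    divergence_between_species: float = 0.15
    fraction_full_length: float = 0.3222
    min_read_length: int = 350
    abundance_sigma: float = 1.2  # lognormal spread of per-type abundances
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "error_rate_sub": self.error_rate_sub,
            "homopolymer_indel_rate": self.homopolymer_indel_rate,
            "ambiguous_rate": self.ambiguous_rate,
            "chimera_fraction": self.chimera_fraction,
            "nonforam_fraction": self.nonforam_fraction,
            "fraction_full_length": self.fraction_full_length,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if not (
            self.divergence_within_type
            < self.divergence_between_types
            < self.divergence_between_species
        ):
            raise ValueError(
                "divergence tiers must satisfy within_type < between_types < between_species"
            )


# size-fraction habitat preference: small fractions are dominated by
# microperforate and basal lineages, the large fraction by spinose and
# non-spinose lineages (weight multipliers per morphogroup).
DEFAULT_FRACTION_BIAS: dict[str, dict[str, float]] = {
    "Spinose": {"20-180": 0.5, ">0.8": 0.5, "180-2000": 4.0},
    "Non-Spinose": {"20-180": 0.5, ">0.8": 0.5, "180-2000": 4.0},
    "Microperforate": {"20-180": 4.0, ">0.8": 4.0, "180-2000": 0.5},
    "Basal": {"20-180": 4.0, ">0.8": 4.0, "180-2000": 0.5},
    "Long-Branch-I": {"20-180": 2.0, ">0.8": 2.0, "180-2000": 0.5},
    "Long-Branch-II": {"20-180": 2.0, ">0.8": 2.0, "180-2000": 0.5},
}


@dataclass
class TruthRecord:
    read_id: str
    sample_id: str
    path: TaxonPath | None  # None for non-foram reads
    reference_id: str
    is_chimera: bool = False
    parent_ids: tuple[str, str] | None = None
    breakpoint: int | None = None  # insert coordinate of the chimeric joint


@dataclass
class SimulatedDataset:
    reads: list[Read]
    tag_map: dict[str, SampleInfo]
    truth: dict[str, TruthRecord]
    references: list[ReferenceSeq]  # foram references (the PFR2-like truth DB)
    outgroups: list[ReferenceSeq]
    taxonomy: TruthTaxonomy
    config: SimulationConfig
    primers: PrimerSet


def _apply_errors(
    seq: str, cfg: SimulationConfig, rng: np.random.Generator
) -> str:
    """454-style noise: uniform substitutions, Ns, and homopolymer indels."""
    if cfg.error_rate_sub == 0 and cfg.ambiguous_rate == 0 and cfg.homopolymer_indel_rate == 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    n = len(seq)
    u = rng.random(n)
    i = 0
    while i < n:
        c = seq[i]
        # homopolymer detection: run length ending at i
        run = 1
        while i - run >= 0 and seq[i - run] == c:
            run += 1
        x = u[i]
        if x < cfg.error_rate_sub:
            out.append(bases[(bases.index(c) + 1 + int(x / cfg.error_rate_sub * 3)) % 4]
                       if c in bases else c)
        elif x < cfg.error_rate_sub + cfg.ambiguous_rate:
            out.append("N")
        elif run >= 3 and x < cfg.error_rate_sub + cfg.ambiguous_rate + cfg.homopolymer_indel_rate:
            # insertion or deletion within the homopolymer, equiprobable
            if x < cfg.error_rate_sub + cfg.ambiguous_rate + cfg.homopolymer_indel_rate / 2:
                out.append(c + c)
            # deletion: append nothing
        else:
            out.append(c)
        i += 1
    return "".join(out)


def simulate_reads(
    taxonomy: TruthTaxonomy,
    references: Sequence[ReferenceSeq],
    config: SimulationConfig,
    outgroups: Sequence[ReferenceSeq] | None = None,
    fraction_bias: Mapping[str, Mapping[str, float]] | None = None,
    primers: PrimerSet | None = None,
) -> SimulatedDataset:
    """Simulate the multiplexed read set, tag map, and ground truth.

    Reads are ``tag + forward primer + insert`` where the insert is a
    (possibly chimeric) copy of a reference, evolved by the within-type
    divergence, truncated unless the read is full length, and degraded by
    sequencing errors.  Deterministic for a fixed config.
    """
    primers = primers or PrimerSet(DEFAULT_FORWARD, DEFAULT_REVERSE)
    outgroups = list(outgroups or [])
    fraction_bias = fraction_bias if fraction_bias is not None else DEFAULT_FRACTION_BIAS
    rng = np.random.default_rng(config.seed)
    foram_refs = list(references)
    if config.chimera_fraction > 0 and len(foram_refs) + len(outgroups) < 2:
        raise ValueError("chimera simulation requires at least 2 references")

    # samples and tags
    combos = list(
        itertools.product(
            range(1, config.n_stations + 1), config.depths, config.size_fractions
        )
    )
    tags = generate_tags(len(combos), length=primers.tag_length, seed=config.seed)
    tag_map: dict[str, SampleInfo] = {}
    for (station, depth, fraction), tag in zip(combos, tags):
        fr_label = fraction.replace(">", "gt").replace("-", "_")
        sid = f"st{station:02d}_{depth}_{fr_label}"
        tag_map[sid] = SampleInfo(
            sample_id=sid, tag=tag, station=f"st{station:02d}", depth=depth,
            size_fraction=fraction,
        )

    # global per-type base abundances (lognormal), biased per size fraction
    base_w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(foram_refs))
    ref_groups = [r.taxon.morphogroup for r in foram_refs]
    rc_rev = _revcomp(primers.reverse)
    template_cache = [encode_dna(r.sequence) for r in foram_refs]
    out_cache = [encode_dna(r.sequence) for r in outgroups]

    reads: list[Read] = []
    truth: dict[str, TruthRecord] = {}
    counter = 0
    for sid, info in tag_map.items():
        w = base_w.copy()
        for k, g in enumerate(ref_groups):
            w[k] *= fraction_bias.get(g, {}).get(info.size_fraction, 1.0)
        w = w * rng.lognormal(0.0, 0.3, size=w.size)  # per-sample noise
        w /= w.sum()
        for _ in range(config.reads_per_sample):
            counter += 1
            rid = f"read{counter:07d}"
            is_outgroup = bool(out_cache) and rng.random() < config.nonforam_fraction
            if is_outgroup:
                k = int(rng.integers(0, len(out_cache)))
                insert_codes = out_cache[k]
                ref = outgroups[k]
                path = None
            else:
                k = int(rng.choice(len(foram_refs), p=w))
                ref = foram_refs[k]
                path = ref.taxon
                insert_codes = template_cache[k]

            is_chimera = (not is_outgroup) and rng.random() < config.chimera_fraction
            parents: tuple[str, str] | None = None
            breakpoint_pos: int | None = None
            if is_chimera:
                k2 = int(rng.choice(len(foram_refs), p=w))
                if k2 == k:
                    k2 = (k + 1) % len(foram_refs)
                L = min(insert_codes.size, template_cache[k2].size)
                lo, hi = int(0.2 * L), int(0.8 * L)
                bp = int(rng.integers(lo, hi))
                insert_codes = np.concatenate(
                    [insert_codes[:bp], template_cache[k2][bp:L]]
                )
                parents = (ref.id, foram_refs[k2].id)
                breakpoint_pos = bp
                path = None

            # within-type biological variability
            insert_codes = evolve_sequence(
                insert_codes, config.divergence_within_type, 2.0, rng
            )
            insert = decode(insert_codes)

            # the sequenced oligo realises each degenerate primer position
            # as a concrete base, so the read never carries ambiguity codes
            rc_concrete = "".join(
                c if c in "ACGT"
                else sorted(IUPAC[c])[int(rng.integers(0, len(IUPAC[c])))]
                for c in rc_rev
            )
            amplicon = info.tag + primers.forward + insert + rc_concrete
            full = rng.random() < config.fraction_full_length
            if not full:
                max_len = len(amplicon) - 1
                min_len = min(config.min_read_length, max_len)
                cut = int(rng.integers(min_len, max_len + 1)) if max_len > min_len else max_len
                amplicon = amplicon[:cut]
            amplicon = _apply_errors(amplicon, config, rng)
            reads.append(Read(id=rid, sequence=amplicon))
            truth[rid] = TruthRecord(
                read_id=rid,
                sample_id=sid,
                path=path,
                reference_id=ref.id,
                is_chimera=is_chimera,
                parent_ids=parents,
                breakpoint=breakpoint_pos,
            )
    return SimulatedDataset(
        reads=reads,
        tag_map=tag_map,
        truth=truth,
        references=foram_refs,
        outgroups=outgroups,
        taxonomy=taxonomy,
        config=config,
        primers=primers,
    )


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "R": "Y", "Y": "R"}
    return "".join(comp.get(c, "N") for c in reversed(seq))


# ---------------------------------------------------------------------------
# Writers (plain-text outputs)


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_tag_map(tag_map: Mapping[str, SampleInfo], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttag\tstation\tdepth\tsize_fraction\n")
        for info in tag_map.values():
            fh.write(
                f"{info.sample_id}\t{info.tag}\t{info.station}\t{info.depth}\t{info.size_fraction}\n"
            )


def write_truth(truth: Mapping[str, TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\ttaxon\treference_id\tis_chimera\tparents\n")
        for rec in truth.values():
            taxon = rec.path.as_string() if rec.path else ""
            parents = ",".join(rec.parent_ids) if rec.parent_ids else ""
            fh.write(
                f"{rec.read_id}\t{rec.sample_id}\t{taxon}\t{rec.reference_id}\t"
                f"{'Y' if rec.is_chimera else 'N'}\t{parents}\n"
            )
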
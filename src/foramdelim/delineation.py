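"""Barcode-gap species delimitation anchored to a reference taxonomy.

The delimitation follows the Automatic Barcode Gap Discovery (ABGD)
logic: pairwise Kimura 1980 (K80) distances are computed between all
sequences; for a sweep of prior maximum intraspecific divergences ``P``
the first sufficiently wide interval ("barcode gap") in the sorted
distance list above ``P`` defines a clustering threshold; partitions are
refined recursively within groups; runs of consecutive priors that yield
the same partition form *plateaus*.

Two taxonomic levels are then picked from the plateaus using sequences
with known taxonomy as anchors: the genetic-type level is the coarsest
(fewest-group) plateau whose partition never co-clusters reference
sequences of distinct genetic types of the same morphospecies, and the
morphospecies level is the coarsest plateau never co-clustering
references of distinct morphospecies.  Environmental sequences inherit
labels from the references they co-cluster with, and groups without
references receive new labels.

The module consumes sequences covering the same region (an alignment or
equal-coordinate fragments); it never aligns.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import ks_2samp, mannwhitneyu

__all__ = [
    "SaturationError",
    "k80_distance",
    "k80_matrix",
    "DistanceMatrix",
    "PartitionSeries",
    "Plateau",
    "abgd_sweep",
    "detect_plateaus",
    "RankAssignment",
    "select_ranks",
    "apply_clade_policy",
    "patristic_validation",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
MIN_RELIABLE_SITES = 100


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the K80 correctable range."""


def k80_distance(a: str, b: str) -> float:
    """Kimura 1980 two-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or ambiguity are excluded
    (pairwise deletion).  With transition proportion P and transversion
    proportion Q over the remaining sites,

        d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

    Raises :class:`SaturationError` when the log argument is non-positive.
    """
    if len(a) != len(b):
        raise ValueError("sequences must cover the same aligned region")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    return k80_from_proportions(ts / n, tv / n)


def k80_from_proportions(P: float, Q: float) -> float:
    """K80 distance from transition (P) and transversion (Q) proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance saturated (P={P:.3f}, Q={Q:.3f}); K80 correction undefined"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    unreliable: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("distance matrix must be finite")


def k80_matrix(ids: Sequence[str], seqs: Sequence[str]) -> DistanceMatrix:
    """Pairwise K80 distances with pairwise deletion.

    Pairs sharing fewer than 100 ungapped sites are flagged unreliable.
    Vectorised over equal-length encoded sequences.
    """
    n = len(ids)
    enc = np.full((n, len(seqs[0])), 255, dtype=np.uint8)
    code = {"A": 0, "G": 1, "C": 2, "T": 3}  # purines < 2 <= pyrimidines
    for i, s in enumerate(seqs):
        if len(s) != len(seqs[0]):
            raise ValueError("sequences must cover the same aligned region")
        arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        for base, c in code.items():
            enc[i, arr == ord(base)] = c
    mat = np.zeros((n, n))
    unreliable: list[tuple[str, str]] = []
    for i in range(n):
        ei = enc[i]
        for j in range(i + 1, n):
            ej = enc[j]
            ok = (ei != 255) & (ej != 255)
            nsites = int(ok.sum())
            if nsites == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            diff = ok & (ei != ej)
            same_class = (ei < 2) == (ej < 2)
            ts = int((diff & same_class).sum())
            tv = int(diff.sum()) - ts
            mat[i, j] = mat[j, i] = k80_from_proportions(ts / nsites, tv / nsites)
            if nsites < MIN_RELIABLE_SITES:
                unreliable.append((ids[i], ids[j]))
    return DistanceMatrix(ids=list(ids), matrix=mat, unreliable=unreliable)


# ---------------------------------------------------------------------------
# ABGD-style sweep


@dataclass
class PartitionSeries:
    """Partitions obtained at each prior of the sweep (priors increasing)."""

    ids: list[str]
    priors: np.ndarray
    partitions: list[tuple[int, ...]]  # canonical group label per sequence

    def group_counts(self) -> list[int]:
        return [len(set(p)) for p in self.partitions]


@dataclass
class Plateau:
    partition: tuple[int, ...]
    prior_lo: float
    prior_hi: float
    span: int  # number of consecutive priors
    n_groups: int


def _canonical(labels: Sequence[int]) -> tuple[int, ...]:
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
        out.append(seen[lab])
    return tuple(out)


def _find_gap_threshold(dists: np.ndarray, prior: float, relative_gap: float) -> float | None:
    """First barcode gap above the prior; returns the clustering threshold.

    ``dists`` is the flat multiset of pairwise distances.  Walking the
    sorted list, a gap is the first interval between consecutive distinct
    values whose upper end exceeds the prior and whose width exceeds
    ``relative_gap`` times the running mean of the distances below it.
    The returned threshold is the gap midpoint (links strictly below it
    fall below the gap).
    """
    s = np.sort(dists)
    if s.size < 2:
        return None
    csum = np.cumsum(s)
    for i in range(s.size - 1):
        width = s[i + 1] - s[i]
        if width <= 0 or s[i + 1] <= prior:
            continue
        running_mean = csum[i] / (i + 1)
        if width > relative_gap * running_mean:
            return float(s[i] + width / 2.0)
    return None


def _split_group(
    idx: np.ndarray,
    D: np.ndarray,
    prior: float,
    relative_gap: float,
    depth: int,
    max_depth: int,
    min_group: int,
) -> list[np.ndarray]:
    if idx.size < min_group or depth >= max_depth:
        return [idx]
    sub = D[np.ix_(idx, idx)]
    pair = sub[np.triu_indices(idx.size, k=1)]
    thr = _find_gap_threshold(pair, prior, relative_gap)
    if thr is None:
        return [idx]
    adj = sub < thr
    groups = _connected_components(adj)
    if len(groups) == 1:
        return [idx]
    out: list[np.ndarray] = []
    for g in groups:
        out.extend(
            _split_group(idx[g], D, prior, relative_gap, depth + 1, max_depth, min_group)
        )
    return out


def _connected_components(adj: np.ndarray) -> list[np.ndarray]:
    n = adj.shape[0]
    label = np.full(n, -1, dtype=int)
    cur = 0
    for start in range(n):
        if label[start] != -1:
            continue
        stack = [start]
        label[start] = cur
        while stack:
            v = stack.pop()
            for w in np.flatnonzero(adj[v]):
                if label[w] == -1:
                    label[w] = cur
                    stack.append(w)
        cur += 1
    return [np.flatnonzero(label == c) for c in range(cur)]


def abgd_sweep(
    D: DistanceMatrix,
    pmin: float = 0.001,
    pmax: float = 0.2,
    steps: int = 100,
    relative_gap: float = 0.5,
    max_depth: int = 10,
    min_group: int = 3,
) -> PartitionSeries:
    """Sweep priors on a log grid and record the partition at each prior.

    At each prior the barcode gap is located in the sorted distance list,
    sequences are clustered by single linkage below the gap, and gap
    detection recurses within groups until no further significant gap is
    found.  Groups smaller than ``min_group`` are never re-split.
    """
    if not (0 < pmin < pmax):
        raise ValueError("require 0 < pmin < pmax")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    priors = np.geomspace(pmin, pmax, steps)
    n = len(D.ids)
    partitions: list[tuple[int, ...]] = []
    for prior in priors:
        groups = _split_group(
            np.arange(n), D.matrix, prior, relative_gap, 0, max_depth, min_group
        )
        labels = np.zeros(n, dtype=int)
        for gi, g in enumerate(groups):
            labels[g] = gi
        partitions.append(_canonical(labels))
    return PartitionSeries(ids=list(D.ids), priors=priors, partitions=partitions)


def detect_plateaus(series: PartitionSeries) -> list[Plateau]:
    """Maximal runs of consecutive priors with identical partitions."""
    plateaus: list[Plateau] = []
    start = 0
    for i in range(1, len(series.partitions) + 1):
        if i == len(series.partitions) or series.partitions[i] != series.partitions[start]:
            part = series.partitions[start]
            plateaus.append(
                Plateau(
                    partition=part,
                    prior_lo=float(series.priors[start]),
                    prior_hi=float(series.priors[i - 1]),
                    span=i - start,
                    n_groups=len(set(part)),
                )
            )
            start = i
    return plateaus


# ---------------------------------------------------------------------------
# Reference-anchored rank selection


@dataclass
class RankAssignment:
    """Per-sequence two-rank labels plus the plateaus that produced them."""

    ids: list[str]
    morphospecies: dict[str, str]
    genetic_type: dict[str, str]
    genetic_plateau: Plateau | None = None
    morphospecies_plateau: Plateau | None = None

    def nested(self) -> bool:
        """True when the genetic-type partition refines the morphospecies one."""
        by_type: dict[str, set[str]] = {}
        for sid in self.ids:
            by_type.setdefault(self.genetic_type[sid], set()).add(
                self.morphospecies[sid]
            )
        return all(len(v) == 1 for v in by_type.values())


def _groups_of(partition: Sequence[int]) -> list[list[int]]:
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(partition):
        groups.setdefault(lab, []).append(i)
    return list(groups.values())


def _admissible_genetic(
    partition: Sequence[int], ref_idx: dict[int, tuple[str, str]]
) -> bool:
    """No group may hold references of distinct genetic types of one morphospecies."""
    for group in _groups_of(partition):
        seen: dict[str, set[str]] = {}
        for i in group:
            if i in ref_idx:
                ms, gt = ref_idx[i]
                seen.setdefault(ms, set()).add(gt)
        if any(len(gts) > 1 for gts in seen.values()):
            return False
    return True


def _admissible_morpho(
    partition: Sequence[int], ref_idx: dict[int, tuple[str, str]]
) -> bool:
    """No group may hold references of distinct morphospecies."""
    for group in _groups_of(partition):
        ms_seen = {ref_idx[i][0] for i in group if i in ref_idx}
        if len(ms_seen) > 1:
            return False
    return True


def _pick_plateau(
    plateaus: Sequence[Plateau],
    admissible,
    rule: str,
) -> Plateau:
    ok = [p for p in plateaus if admissible(p.partition)]
    if not ok:
        warnings.warn("no admissible plateau; falling back to the finest partition")
        return min(plateaus, key=lambda p: -p.n_groups)
    if rule == "coarsest_admissible":
        return min(ok, key=lambda p: (p.n_groups, -p.span, p.prior_lo))
    if rule == "longest_span_admissible":
        return min(ok, key=lambda p: (-p.span, p.n_groups, p.prior_lo))
    raise ValueError(f"unknown plateau rule {rule!r}")


def _letters() -> Iterable[str]:
    for size in range(1, 4):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def select_ranks(
    plateaus: Sequence[Plateau],
    ids: Sequence[str],
    ref_labels: Mapping[str, tuple[str, str]],
    plateau_rule: str = "coarsest_admissible",
    novel_prefix: str = "Novel",
) -> RankAssignment:
    """Anchor the two taxonomic levels to reference labels.

    ``ref_labels`` maps reference sequence ids to (morphospecies,
    genetic_type).  Groups containing references inherit their labels;
    reference-free groups are named ``"<novel_prefix> A"``, ``"... B"``
    etc. at the morphospecies level and ``"<morphospecies>-1"`` ... at
    the genetic-type level within each morphospecies.
    """
    if not plateaus:
        raise ValueError("empty plateau list")
    idx_of = {sid: i for i, sid in enumerate(ids)}
    ref_idx = {idx_of[r]: lab for r, lab in ref_labels.items() if r in idx_of}

    ms_plat = _pick_plateau(plateaus, lambda p: _admissible_morpho(p, ref_idx), plateau_rule)
    gt_plat = _pick_plateau(plateaus, lambda p: _admissible_genetic(p, ref_idx), plateau_rule)

    gt_part = list(gt_plat.partition)
    ms_part = list(ms_plat.partition)
    # enforce nesting: refine the genetic-type partition by the morphospecies one
    n_ms = max(ms_part) + 1
    gt_part = _canonical([g * n_ms + m for g, m in zip(gt_part, ms_part)])

    letters = iter(_letters())
    ms_labels: dict[int, str] = {}
    for group in _groups_of(ms_part):
        lab = ms_part[group[0]]
        names = {ref_idx[i][0] for i in group if i in ref_idx}
        ms_labels[lab] = sorted(names)[0] if names else f"{novel_prefix} {next(letters)}"

    morphospecies = {ids[i]: ms_labels[ms_part[i]] for i in range(len(ids))}

    # genetic-type labels are qualified by morphospecies: the same bare
    # type name (e.g. "Type I") recurs in many species of the field's
    # nomenclature and only identifies a lineage within its species
    gt_labels: dict[int, str] = {}
    novel_counter: dict[str, int] = {}
    for group in _groups_of(gt_part):
        lab = gt_part[group[0]]
        ms_name = morphospecies[ids[group[0]]]
        names = {ref_idx[i][1] for i in group if i in ref_idx}
        if names:
            gt_labels[lab] = f"{ms_name} {sorted(names)[0]}"
        else:
            novel_counter[ms_name] = novel_counter.get(ms_name, 0) + 1
            gt_labels[lab] = f"{ms_name}-{novel_counter[ms_name]}"

    genetic_type = {ids[i]: gt_labels[gt_part[i]] for i in range(len(ids))}
    assignment = RankAssignment(
        ids=list(ids),
        morphospecies=morphospecies,
        genetic_type=genetic_type,
        genetic_plateau=gt_plat,
        morphospecies_plateau=ms_plat,
    )
    assert assignment.nested(), "genetic types must nest within morphospecies"
    return assignment


def apply_clade_policy(
    assignment: RankAssignment,
    clade_of: Mapping[str, str],
    policies: Mapping[str, str],
) -> RankAssignment:
    """Apply per-clade overrides, e.g. collapsing genetic types.

    ``policies`` maps clade name to a policy; the only recognised policy
    is ``"collapse_genetic_types"``, which sets each sequence's genetic
    type to its morphospecies label — the conservative reading for clades
    whose apparent sub-species variation may be intragenomic.
    """
    known_clades = set(clade_of.values())
    for clade, policy in policies.items():
        if clade not in known_clades:
            raise ValueError(f"policy references unknown clade {clade!r}")
        if policy != "collapse_genetic_types":
            raise ValueError(f"unknown clade policy {policy!r}")
    genetic = dict(assignment.genetic_type)
    for sid in assignment.ids:
        clade = clade_of.get(sid)
        if clade is not None and policies.get(clade) == "collapse_genetic_types":
            genetic[sid] = assignment.morphospecies[sid]
    return RankAssignment(
        ids=list(assignment.ids),
        morphospecies=dict(assignment.morphospecies),
        genetic_type=genetic,
        genetic_plateau=assignment.genetic_plateau,
        morphospecies_plateau=assignment.morphospecies_plateau,
    )


# ---------------------------------------------------------------------------
# Patristic validation


@dataclass
class PatristicValidation:
    intra_type: np.ndarray
    inter_type_intra_species: np.ndarray
    inter_species: np.ndarray
    ks_type_vs_intertype: tuple[float, float]  # statistic, p-value
    ks_intertype_vs_interspecies: tuple[float, float]
    mw_type_vs_intertype: tuple[float, float]
    mw_intertype_vs_interspecies: tuple[float, float]


def patristic_validation(tree, assignment: RankAssignment) -> PatristicValidation:
    """Compare patristic-distance distributions between taxonomic classes.

    ``tree`` is a dendropy Tree (or a newick string/path, loaded here)
    whose tips cover the assigned sequences.  Pairwise tip-to-tip path
    lengths are split into intra-genetic-type, inter-type-intra-species
    and inter-species classes, and consecutive classes are compared with
    two-sample Kolmogorov-Smirnov and Mann-Whitney tests.
    """
    import dendropy

    if isinstance(tree, (str, bytes)):
        s = str(tree)
        if "(" in s:
            tree = dendropy.Tree.get(data=s, schema="newick")
        else:
            tree = dendropy.Tree.get(path=s, schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [sid for sid in assignment.ids if sid not in tips]
    if missing:
        raise ValueError(f"tree is missing tips for: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    classes: dict[str, list[float]] = {"intra": [], "inter_type": [], "inter_species": []}
    ids = assignment.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            if assignment.genetic_type[a] == assignment.genetic_type[b]:
                classes["intra"].append(d)
            elif assignment.morphospecies[a] == assignment.morphospecies[b]:
                classes["inter_type"].append(d)
            else:
                classes["inter_species"].append(d)

    def _tests(x, y):
        if len(x) == 0 or len(y) == 0:
            return (math.nan, math.nan), (math.nan, math.nan)
        ks = ks_2samp(x, y)
        mw = mannwhitneyu(x, y, alternative="two-sided")
        return (float(ks.statistic), float(ks.pvalue)), (float(mw.statistic), float(mw.pvalue))

    ks1, mw1 = _tests(classes["intra"], classes["inter_type"])
    ks2, mw2 = _tests(classes["inter_type"], classes["inter_species"])
    return PatristicValidation(
        intra_type=np.array(classes["intra"]),
        inter_type_intra_species=np.array(classes["inter_type"]),
        inter_species=np.array(classes["inter_species"]),
        ks_type_vs_intertype=ks1,
        ks_intertype_vs_interspecies=ks2,
        mw_type_vs_intertype=mw1,
        mw_intertype_vs_interspecies=mw2,
    )
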
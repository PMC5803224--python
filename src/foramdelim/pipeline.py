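"""End-to-end orchestration of the metabarcoding inference chain.

Chains the stages in the order used for the foraminiferal survey:

1. simulate (or load) multiplexed reads,
2. demultiplex, primer-filter, trim to 300 bp,
3. dereplicate and screen chimeras,
4. single-linkage clustering at d = 2 into MOTUs,
5. best-hit assignment and removal of non-foraminiferal MOTUs,
6. occurrence/abundance filtering (>= 3 samples, >= 10 reads) and
   representative selection,
7. reference-anchored two-rank delimitation per morphogroup clade,
8. meta-reference construction and >95% reassignment of all MOTUs,
9. ecological table, rarefaction and composition summaries,

and, when ground truth is available, evaluates chimera detection and
taxonomic recovery (adjusted Rand index at both ranks).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import chimera as chimera_mod
from . import clustering, delineation, ecology, readprep, synthdata, taxonomy
from .taxon import ReferenceSeq, TaxonPath


@dataclass
class PipelineResult:
    n_raw_reads: int
    n_retained_reads: int
    reverse_primer_fraction: float
    n_amplicons: int
    n_chimera_flagged: int
    n_motus: int
    n_nonforam_motus: int
    n_foram_motus: int
    n_abundant_motus: int
    n_rare_motus: int
    n_foram_reads: int
    rank_assignment: delineation.RankAssignment | None
    n_genetic_types: int
    n_morphospecies: int
    meta_unique_paths: int
    ecological: taxonomy.EcologicalDataset
    table: pd.DataFrame
    metadata: pd.DataFrame
    reassigned_read_fraction: float
    evaluation: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    dataset: synthdata.SimulatedDataset,
    d: int = 2,
    trim_length: int = 300,
    min_samples: int = 3,
    min_reads: int = 10,
    reassign_threshold: float = 95.0,
    abgd_steps: int = 100,
    relative_gap: float = 0.5,
    evaluate: bool = True,
) -> PipelineResult:
    """Run the full chain on a simulated dataset and summarise it."""
    primers = dataset.primers

    # --- read preparation ---------------------------------------------------
    prep = readprep.prep_reads(
        dataset.reads, dataset.tag_map, primers, trim_length=trim_length
    )

    # --- dereplication and chimera screen ------------------------------------
    amplicons = chimera_mod.dereplicate(prep.trimmed)
    verdicts = chimera_mod.detect_chimeras(amplicons)
    clean, flagged = chimera_mod.remove_chimeras(amplicons, verdicts)

    # --- clustering -----------------------------------------------------------
    motus = clustering.swarm_cluster(clean, d=d)

    # --- PR2-style screening --------------------------------------------------
    pr2like = _truncate_refs(dataset.references + dataset.outgroups, trim_length)
    assignments = taxonomy.assign_motus(motus, pr2like)
    foram_motus, nonforam = taxonomy.screen_nonforam(motus, assignments, pr2like)

    # --- abundance/occurrence filter and representatives ----------------------
    abundant, rare = clustering.abundance_occurrence_filter(
        foram_motus, min_samples=min_samples, min_reads=min_reads
    )
    clustering.assign_representatives(abundant, prep.untrimmed_retained)

    # --- delimitation per clade ------------------------------------------------
    ref_by_id = {r.id: r for r in dataset.references}
    clade_of_motu = {
        m.id: ref_by_id[assignments[m.id].best_hit_id].taxon.morphogroup
        for m in abundant
    }
    rank_assignment = delineate_by_clade(
        abundant,
        dataset.references,
        clade_of_motu,
        trim_length=trim_length,
        steps=abgd_steps,
        relative_gap=relative_gap,
    )

    # --- meta-reference and reassignment --------------------------------------
    genus_of_ms = {
        r.taxon.morphospecies: (r.taxon.morphogroup, r.taxon.genus)
        for r in dataset.references
    }
    env_reps = []
    for m in abundant:
        ms = rank_assignment.morphospecies[m.id]
        gt = rank_assignment.genetic_type[m.id]
        # the path stores the bare type name; the qualified label only
        # disambiguates identically named types of different species
        bare_gt = gt[len(ms) + 1:] if gt.startswith(ms + " ") else gt
        group, genus = genus_of_ms.get(
            ms, (clade_of_motu[m.id], f"{clade_of_motu[m.id]}_env")
        )
        env_reps.append(
            ReferenceSeq(
                id=m.id,
                sequence=m.representative or m.seed_sequence,
                path=("Eukaryota", "Rhizaria", "Foraminifera", group, genus, ms, bare_gt),
                source="environmental",
            )
        )
    meta = taxonomy.build_meta_reference(dataset.references, [], env_reps)
    ecological = taxonomy.reassign_all(
        foram_motus, meta, threshold=reassign_threshold
    )

    # --- ecology ----------------------------------------------------------------
    table = ecology.build_table(ecological, dataset.tag_map)
    metadata = ecology.sample_metadata(dataset.tag_map)

    foram_reads = sum(m.total_reads for m in foram_motus)
    reassigned_fraction = (
        ecological.total_reads / foram_reads if foram_reads else 0.0
    )

    result = PipelineResult(
        n_raw_reads=len(dataset.reads),
        n_retained_reads=len(prep.trimmed),
        reverse_primer_fraction=prep.reverse_primer_fraction,
        n_amplicons=len(amplicons),
        n_chimera_flagged=len(flagged),
        n_motus=len(motus),
        n_nonforam_motus=len(nonforam),
        n_foram_motus=len(foram_motus),
        n_abundant_motus=len(abundant),
        n_rare_motus=len(rare),
        n_foram_reads=foram_reads,
        rank_assignment=rank_assignment,
        n_genetic_types=len(
            {rank_assignment.genetic_type[m.id] for m in abundant}
        ),
        n_morphospecies=len(
            {rank_assignment.morphospecies[m.id] for m in abundant}
        ),
        meta_unique_paths=meta.n_unique_paths,
        ecological=ecological,
        table=table,
        metadata=metadata,
        reassigned_read_fraction=reassigned_fraction,
    )
    if evaluate:
        result.evaluation = evaluate_against_truth(
            dataset, prep, amplicons, verdicts, abundant, rank_assignment
        )
    return result


def _truncate_refs(refs: Sequence[ReferenceSeq], length: int) -> list[ReferenceSeq]:
    return [
        ReferenceSeq(id=r.id, sequence=r.sequence[:length], path=r.path, source=r.source)
        for r in refs
    ]


def delineate_by_clade(
    motus: Sequence[clustering.MOTU],
    references: Sequence[ReferenceSeq],
    clade_of_motu: Mapping[str, str],
    trim_length: int = 300,
    steps: int = 100,
    relative_gap: float = 0.5,
) -> delineation.RankAssignment:
    """Run the ABGD sweep and rank selection within each morphogroup clade.

    Crown groups of closely related sequences are delimited separately:
    saturation between distant morphogroups would otherwise dominate the
    distance distribution.  Environmental MOTU seeds are pooled with the
    clade's reference sequences (truncated to the same 300 bp region) and
    labels are merged across clades.
    """
    morphospecies: dict[str, str] = {}
    genetic_type: dict[str, str] = {}
    all_ids: list[str] = []
    clades = sorted({*clade_of_motu.values()})
    for clade in clades:
        clade_motus = [m for m in motus if clade_of_motu[m.id] == clade]
        clade_refs = [r for r in references if r.taxon.morphogroup == clade]
        ids = [r.id for r in clade_refs] + [m.id for m in clade_motus]
        seqs = [r.sequence[:trim_length] for r in clade_refs] + [
            m.seed_sequence[:trim_length] for m in clade_motus
        ]
        ref_labels = {
            r.id: (r.taxon.morphospecies, r.taxon.genetic_type) for r in clade_refs
        }
        if len(ids) < 3:
            # too small for gap detection: inherit nearest-reference labels
            for m in clade_motus:
                if clade_refs:
                    morphospecies[m.id] = clade_refs[0].taxon.morphospecies
                    genetic_type[m.id] = clade_refs[0].taxon.genetic_type
                else:
                    morphospecies[m.id] = f"{clade} A"
                    genetic_type[m.id] = f"{clade} A-1"
                all_ids.append(m.id)
            for r in clade_refs:
                morphospecies[r.id] = r.taxon.morphospecies
                genetic_type[r.id] = r.taxon.genetic_type
                all_ids.append(r.id)
            continue
        D = delineation.k80_matrix(ids, seqs)
        series = delineation.abgd_sweep(
            D, steps=steps, relative_gap=relative_gap
        )
        plateaus = delineation.detect_plateaus(series)
        assignment = delineation.select_ranks(
            plateaus, ids, ref_labels, novel_prefix=clade
        )
        morphospecies.update(assignment.morphospecies)
        genetic_type.update(assignment.genetic_type)
        all_ids.extend(ids)
    return delineation.RankAssignment(
        ids=all_ids, morphospecies=morphospecies, genetic_type=genetic_type
    )


def chimera_confusion(
    dataset: synthdata.SimulatedDataset,
    trimmed_reads: Sequence[readprep.Read],
    amplicons: Sequence[chimera_mod.Amplicon],
    verdicts: Sequence[chimera_mod.ChimeraVerdict],
    margin: int = 50,
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) of the chimera screen against ground truth.

    A chimeric read only counts as a detectable positive when its
    breakpoint leaves at least ``margin`` bp of *each* parent inside the
    analysed trimmed window; a chimera whose joint falls outside the
    window is, within that window, a faithful copy of one parent and is
    excluded from both the positive and the negative class.
    """
    truth = dataset.truth
    window = len(trimmed_reads[0].sequence) if trimmed_reads else 300

    def _read_class(rid: str) -> int:
        rec = truth[rid]
        if not rec.is_chimera:
            return 0
        bp = rec.breakpoint if rec.breakpoint is not None else 0
        return 1 if margin <= bp <= window - margin else 2

    seq_truth: dict[str, Counter] = {}
    for read in trimmed_reads:
        seq_truth.setdefault(read.sequence, Counter())[_read_class(read.id)] += 1

    tp = fp = fn = tn = 0
    flagged = {v.query_id for v in verdicts if v.is_chimera}
    for a in amplicons:
        votes = seq_truth.get(a.sequence, Counter())
        if not votes:
            continue
        cls = votes.most_common(1)[0][0]
        if cls == 2:
            continue
        if a.id in flagged:
            tp += cls == 1
            fp += cls == 0
        else:
            fn += cls == 1
            tn += cls == 0
    return tp, fp, fn, tn


def evaluate_against_truth(
    dataset: synthdata.SimulatedDataset,
    prep: readprep.PrepResult,
    amplicons: Sequence[chimera_mod.Amplicon],
    verdicts: Sequence[chimera_mod.ChimeraVerdict],
    abundant: Sequence[clustering.MOTU],
    rank_assignment: delineation.RankAssignment,
) -> dict[str, float]:
    """Score chimera detection and taxonomic recovery against ground truth."""
    truth = dataset.truth
    tp, fp, fn, tn = chimera_confusion(dataset, prep.trimmed, amplicons, verdicts)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    read_by_id = {read.id: read.sequence for read in prep.trimmed}

    # per-MOTU true genetic type by majority over member reads
    read_truth_seq: dict[str, Counter] = {}
    for rid, seq in read_by_id.items():
        rec = truth[rid]
        if rec.path is not None and not rec.is_chimera:
            read_truth_seq.setdefault(seq, Counter())[rec.path] += 1

    true_gt: list[str] = []
    true_ms: list[str] = []
    pred_gt: list[str] = []
    pred_ms: list[str] = []
    for m in abundant:
        votes = Counter()
        for a in m.members:
            votes.update(read_truth_seq.get(a.sequence, Counter()))
        if not votes:
            continue
        path = votes.most_common(1)[0][0]
        true_gt.append(path.as_string())
        true_ms.append(f"{path.morphogroup}|{path.genus}|{path.morphospecies}")
        pred_gt.append(rank_assignment.genetic_type[m.id])
        pred_ms.append(rank_assignment.morphospecies[m.id])

    ari_gt = adjusted_rand_score(true_gt, pred_gt) if true_gt else float("nan")
    ari_ms = adjusted_rand_score(true_ms, pred_ms) if true_ms else float("nan")
    return {
        "chimera_sensitivity": float(sensitivity),
        "chimera_fpr": float(fpr),
        "ari_genetic_type": float(ari_gt),
        "ari_morphospecies": float(ari_ms),
        "n_scored_motus": float(len(true_gt)),
    }
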
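"""Global-identity assignment, screening, meta-reference and reassignment."""

from __future__ import annotations

import random

import pytest

from foramdelim.chimera import Amplicon
from foramdelim.clustering import MOTU
from foramdelim.taxon import ReferenceSeq, TaxonPath
from foramdelim.taxonomy import (
    MetaReference,
    assign,
    assign_motus,
    build_meta_reference,
    global_identity,
    reassign_all,
    screen_nonforam,
)

FORAM_PREFIX = ("Eukaryota", "Rhizaria", "Foraminifera")


def _ref(rid, seq, *ranks, foram=True):
    head = FORAM_PREFIX if foram else ("Eukaryota", "Stramenopiles", "Bacillariophyta")
    return ReferenceSeq(id=rid, sequence=seq, path=head + tuple(ranks))


def _rand(rng, n=300):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mut(rng, seq, k):
    out = list(seq)
    for pos in rng.sample(range(len(seq)), k):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("ACGT" * 75, "ACGT" * 75) == 100.0

    def test_fifteen_substitutions_in_300(self):
        rng = random.Random(0)
        a = _rand(rng)
        b = _mut(rng, a, 15)
        assert global_identity(a, b) == pytest.approx(95.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("ACGT", "")

    def test_symmetry(self):
        rng = random.Random(1)
        for _ in range(5):
            a, b = _rand(rng, 80), _rand(rng, 90)
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))


class TestAssign:
    def test_exact_hit_unambiguous(self):
        rng = random.Random(2)
        seq = _rand(rng)
        refs = [
            _ref("r1", seq, "Spinose", "G", "sp1", "T1"),
            _ref("r2", _mut(rng, seq, 30), "Spinose", "G", "sp2", "T1"),
        ]
        a = assign("q", seq, refs)
        assert a.best_hit_id == "r1"
        assert a.identity == 100.0
        assert not a.ambiguous

    def test_equidistant_conflicting_paths_is_ambiguous(self):
        rng = random.Random(3)
        seq = _rand(rng)
        refs = [
            _ref("foram", seq, "Spinose", "G", "sp1", "T1"),
            _ref("diatom", seq, "Diatomea", "D", "dsp", "T1", foram=False),
        ]
        a = assign("q", seq, refs)
        assert a.ambiguous

    def test_tie_within_morphospecies_resolves_to_unresolved_type(self):
        rng = random.Random(4)
        seq = _rand(rng)
        refs = [
            _ref("r1", seq, "Spinose", "G", "sp1", "T1"),
            _ref("r2", seq, "Spinose", "G", "sp1", "T2"),
        ]
        a = assign("q", seq, refs)
        assert not a.ambiguous
        assert a.path[-1] == "unresolved"

    def test_best_hit_table_matches_brute_force(self):
        rng = random.Random(5)
        refs = [
            _ref(f"r{i}", _rand(rng), "Spinose", "G", f"sp{i}", "T1")
            for i in range(8)
        ]
        for i in range(20):
            base = rng.choice(refs)
            q = _mut(rng, base.sequence, rng.randint(0, 20))
            got = assign(f"q{i}", q, refs)
            brute = max(refs, key=lambda r: global_identity(q, r.sequence))
            assert got.best_hit_id == brute.id

    def test_empty_refdb_rejected(self):
        with pytest.raises(ValueError):
            assign("q", "ACGT", [])


class TestScreenNonforam:
    def test_mixed_set_partitioned_correctly(self):
        rng = random.Random(6)
        foram_seq, diatom_seq = _rand(rng), _rand(rng)
        refs = [
            _ref("f", foram_seq, "Spinose", "G", "sp1", "T1"),
            _ref("d", diatom_seq, "Diatomea", "D", "dsp", "T1", foram=False),
        ]
        motus = []
        n_foram_truth = 0
        for i in range(10):
            src = foram_seq if i % 3 else diatom_seq
            n_foram_truth += 1 if i % 3 else 0
            motus.append(
                MOTU(f"m{i}", [Amplicon(f"a{i}", _mut(rng, src, 2), 5, {"s": 5})],
                     _mut(rng, src, 2))
            )
        assignments = assign_motus(motus, refs)
        foram, discarded = screen_nonforam(motus, assignments, refs)
        assert len(foram) == n_foram_truth
        assert len(discarded) == 10 - n_foram_truth


class TestMetaReference:
    def test_distinct_paths_counted(self):
        rng = random.Random(7)
        refs = [_ref(f"r{i}", _rand(rng), "Spinose", "G", f"sp{i}", "T1") for i in range(3)]
        env = [
            ReferenceSeq(f"m{i}", _rand(rng),
                         FORAM_PREFIX + ("Spinose", "G", f"env{i}", "T1"))
            for i in range(2)
        ]
        meta = build_meta_reference(refs, [], env)
        assert len(meta.refs) == 5
        assert meta.n_unique_paths == 5

    def test_shared_path_does_not_add(self):
        rng = random.Random(8)
        seq = _rand(rng)
        ref = _ref("r1", seq, "Spinose", "G", "sp1", "T1")
        env = ReferenceSeq("m1", _mut(rng, seq, 3),
                           FORAM_PREFIX + ("Spinose", "G", "sp1", "T1"))
        meta = build_meta_reference([ref], [], [env])
        assert meta.n_unique_paths == 1
        assert not meta.warnings

    def test_conflicting_same_path_sequences_warn(self):
        rng = random.Random(9)
        ref = _ref("r1", _rand(rng), "Spinose", "G", "sp1", "T1")
        env = ReferenceSeq("m1", _rand(rng),
                           FORAM_PREFIX + ("Spinose", "G", "sp1", "T1"))
        meta = build_meta_reference([ref], [], [env])
        assert meta.warnings

    def test_duplicate_ids_rejected(self):
        rng = random.Random(10)
        r = _ref("dup", _rand(rng), "Spinose", "G", "sp1", "T1")
        with pytest.raises(ValueError, match="duplicate"):
            build_meta_reference([r], [], [r])


class TestReassignAll:
    def _setup(self, rng):
        seq = _rand(rng)
        ref = _ref("r1", seq, "Spinose", "G", "sp1", "T1")
        meta = build_meta_reference([ref], [], [])
        return seq, meta

    def test_identity_at_threshold_excluded_strict(self):
        rng = random.Random(11)
        seq, meta = self._setup(rng)
        # exactly 95.0% identity: 15 substitutions in 300
        query = _mut(rng, seq, 15)
        m = MOTU("m1", [Amplicon("a1", query, 5, {"s": 5})], query)
        out = reassign_all([m], meta, threshold=95.0)
        assert out.retained_motus == []
        out_inc = reassign_all([m], meta, threshold=95.0, inclusive=True)
        assert out_inc.retained_motus == ["m1"]

    def test_just_below_threshold_excluded(self):
        rng = random.Random(12)
        seq, meta = self._setup(rng)
        query = _mut(rng, seq, 16)  # 94.7%
        m = MOTU("m1", [Amplicon("a1", query, 5, {"s": 5})], query)
        out = reassign_all([m], meta, threshold=95.0)
        assert out.retained_motus == []

    def test_rare_motu_inherits_reference_only_taxon(self):
        rng = random.Random(13)
        seq, meta = self._setup(rng)
        query = _mut(rng, seq, 3)  # 99%
        m = MOTU("m1", [Amplicon("a1", query, 2, {"s": 2})], query)
        out = reassign_all([m], meta)
        assert out.retained_motus == ["m1"]
        taxon = out.taxa[0]
        assert taxon.morphospecies == "sp1"

    def test_merging_conserves_reads(self):
        rng = random.Random(14)
        seq, meta = self._setup(rng)
        motus = [
            MOTU("m1", [Amplicon("a1", _mut(rng, seq, 2), 7, {"s1": 7})], _mut(rng, seq, 2)),
            MOTU("m2", [Amplicon("a2", _mut(rng, seq, 3), 4, {"s2": 4})], _mut(rng, seq, 3)),
            MOTU("m3", [Amplicon("a3", _rand(rng), 9, {"s1": 9})], _rand(rng)),
        ]
        out = reassign_all(motus, meta)
        excluded_reads = sum(
            m.total_reads for m in motus
            if m.id in {mid for mid, _ in out.excluded_motus}
        )
        assert out.total_reads + excluded_reads == sum(m.total_reads for m in motus)
        # m1 and m2 share the path: merged into one row
        assert len(out.taxa) == 1
        assert out.counts[out.taxa[0]] == {"s1": 7, "s2": 4}

    def test_environmental_representatives_self_assign(self, pipeline_result):
        """Every retained MOTU rep present in the meta-reference assigns to
        itself at 100% and is retained in the ecological dataset."""
        eco = pipeline_result.ecological
        retained = set(eco.retained_motus)
        # all abundant MOTUs (they seeded the meta-reference) are retained
        assert pipeline_result.n_abundant_motus <= len(retained)
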
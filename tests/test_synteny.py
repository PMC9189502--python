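"""Synteny-block inference: examples, invariants, and oracle equivalence."""

import numpy as np
import pytest

from skit.paf import AlignmentRecord
from skit.simgenome import (SimNode, StructuralEvent, emit_truth_alignments,
                            random_chromosome, simulate_allele_histories)
from skit.synteny import (DEFAULT_SCHEDULE, MergeSchedule,
                          classify_rearrangements, filter_alignments,
                          iterative_synteny, merge_blocks, split_subblocks)
from .oracles import oracle_iterative, oracle_merge, oracle_split


def rec(rs, re, qs, qe, strand="+", q="q", dv=None, ref="ref"):
    return AlignmentRecord(ref_name=ref, ref_start=rs, ref_end=re,
                           query_name=q, query_start=qs, query_end=qe,
                           strand=strand, dv=dv)


def random_records(rng, n_max=50, span=5_000, queries=("q1", "q2")):
    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        length = int(rng.integers(1, span // 4))
        rs = int(rng.integers(0, span - length))
        qs = int(rng.integers(0, span))
        qlen = max(1, int(length * rng.uniform(0.5, 2.0)))
        out.append(rec(rs, rs + length, qs, qs + qlen,
                       strand=str(rng.choice(["+", "-"])),
                       q=str(rng.choice(queries))))
    return out


class TestFilterAlignments:
    def test_min_length_boundary_inclusive(self):
        records = [rec(0, 400, 0, 400), rec(0, 500, 0, 500),
                   rec(0, 9_000, 0, 9_000)]
        kept = filter_alignments(records, min_length=500)
        assert [r.ref_end for r in kept] == [500, 9_000]

    def test_dv_filter_keeps_low_divergence(self):
        r = rec(0, 3_000, 0, 3_000, dv=0.35)
        assert filter_alignments([r], min_length=2_000, max_dv=0.2) == []
        r2 = rec(0, 3_000, 0, 3_000, dv=0.1)
        assert filter_alignments([r2], min_length=2_000, max_dv=0.2) == [r2]

    def test_record_without_dv_dropped_under_dv_filter(self, caplog):
        r = rec(0, 3_000, 0, 3_000)
        with caplog.at_level("WARNING"):
            assert filter_alignments([r], max_dv=0.2) == []
        assert "no dv tag" in caplog.text
        assert filter_alignments([r]) == [r]   # inactive filter keeps it

    def test_empty_input(self):
        assert filter_alignments([], 500, 0.2) == []


class TestSplitSubblocks:
    def test_two_overlapping_alignments_four_subblocks(self):
        a, b = rec(0, 1_000, 0, 1_000), rec(500, 1_500, 2_000, 3_000)
        got = {(s.ref_start, s.ref_end, s.parent) for s in
               split_subblocks([a, b])}
        assert got == {(0, 500, 0), (500, 1_000, 0),
                       (500, 1_000, 1), (1_000, 1_500, 1)}

    def test_single_alignment_identity(self):
        a = rec(10, 200, 50, 240)
        (sb,) = split_subblocks([a])
        assert (sb.ref_start, sb.ref_end) == (10, 200)
        assert (sb.query_start, sb.query_end) == (50, 240)

    def test_minus_strand_interpolation(self):
        """Splitting a − alignment keeps the query interval mirrored: the
        left ref piece takes the right query piece."""
        a = rec(0, 100, 200, 300, strand="-")
        b = rec(50, 150, 500, 600)   # forces a cut at ref 50
        subs = [s for s in split_subblocks([a, b]) if s.parent == 0]
        by_ref = {s.ref_start: s for s in subs}
        assert (by_ref[0].query_start, by_ref[0].query_end) == (250, 300)
        assert (by_ref[50].query_start, by_ref[50].query_end) == (200, 250)

    def test_split_matches_bruteforce_segmentation(self, rng):
        for _ in range(25):
            records = random_records(rng, n_max=12, span=800)
            mine = [(s.ref_start, s.ref_end, s.query_name, s.query_start,
                     s.query_end, s.strand, s.parent)
                    for s in split_subblocks(records)]
            assert mine == oracle_split(records)


class TestMergeBlocks:
    def test_small_gap_single_block(self):
        subs = split_subblocks([rec(0, 300, 0, 300),
                                rec(400, 2_600, 400, 2_600)])
        (blk,) = merge_blocks(subs, min_size=100, max_distance=100_000)
        assert (blk.ref_start, blk.ref_end) == (0, 2_600)

    def test_strand_mismatch_two_blocks(self):
        subs = split_subblocks([rec(0, 300, 0, 300),
                                rec(400, 900, 400, 900, strand="-")])
        assert len(merge_blocks(subs, 100, 100_000)) == 2

    def test_min_size_discards(self):
        subs = split_subblocks([rec(0, 150, 0, 150)])
        assert merge_blocks(subs, 200, 100_000) == []

    def test_query_name_partition(self):
        subs = split_subblocks([rec(0, 300, 0, 300, q="q1"),
                                rec(400, 900, 0, 500, q="q2")])
        assert len(merge_blocks(subs, 100, 100_000)) == 2
        assert len(merge_blocks(subs, 100, 100_000,
                                require_same_query=False)) == 1


class TestIterativeSynteny:
    def test_one_iteration_is_split_plus_merge(self, rng):
        for _ in range(10):
            records = random_records(rng, n_max=15, span=1_000)
            one = iterative_synteny(records, MergeSchedule((5,), 100),
                                    max_query_gap=100)
            direct = merge_blocks(split_subblocks(records), 5, 100,
                                  max_query_gap=100)
            assert [(b.ref_start, b.ref_end, b.query_name, b.query_start,
                     b.query_end, b.strand) for b in one] == \
                   [(b.ref_start, b.ref_end, b.query_name, b.query_start,
                     b.query_end, b.strand) for b in direct]

    def test_unrearranged_pair_one_nearly_full_block(self, rng):
        anc = random_chromosome("anc", 500_000, rng)
        tree = SimNode("root", children=[
            SimNode("ref"), SimNode("alt", subs_rate=0.02)])
        tips = simulate_allele_histories(anc, tree, rng)
        recs = emit_truth_alignments(tips["ref"], tips["alt"], 200)
        blocks = iterative_synteny(recs)
        assert len(blocks) == 1
        assert blocks[0].ref_span >= 0.99 * 500_000
        assert blocks[0].level == DEFAULT_SCHEDULE.n_iterations

    def test_simulated_inversion_recovered_at_block_resolution(self, rng):
        anc = random_chromosome("anc", 1_000_000, rng)
        tree = SimNode("root", children=[
            SimNode("ref"),
            SimNode("alt", subs_rate=0.02, events=[
                StructuralEvent("inversion", 250_000, 750_000)])])
        tips = simulate_allele_histories(anc, tree, rng)
        recs = emit_truth_alignments(tips["ref"], tips["alt"], 200)
        blocks = iterative_synteny(recs)
        minus = [b for b in blocks if b.strand == "-"]
        assert len(minus) == 1
        assert abs(minus[0].ref_start - 250_000) <= 20_000
        assert abs(minus[0].ref_end - 750_000) <= 20_000

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(40):
            records = random_records(rng)
            mine = [(b.ref_start, b.ref_end, b.query_name, b.query_start,
                     b.query_end, b.strand)
                    for b in iterative_synteny(
                        records, MergeSchedule((5, 20, 80), 100))]
            assert mine == oracle_iterative(records, (5, 20, 80), 100)

    def test_coverage_monotone_and_min_size_never_adds_blocks(self, rng):
        for _ in range(15):
            records = random_records(rng, n_max=20, span=2_000)
            covered_in = np.zeros(5_000, bool)
            for r in records:
                covered_in[r.ref_start:r.ref_end] = True
            subs = split_subblocks(records)
            prev_count = None
            for min_size in (5, 20, 80):
                blocks = merge_blocks(subs, min_size, 100)
                covered_out = np.zeros(5_000, bool)
                for b in blocks:
                    for m in b.members:
                        covered_out[m.ref_start:m.ref_end] = True
                assert not (covered_out & ~covered_in).any()
                count = sum(len(b.members) for b in blocks)
                if prev_count is not None:
                    assert count <= prev_count
                prev_count = count

    def test_internal_gaps_respect_max_distance(self, rng):
        for _ in range(15):
            records = random_records(rng)
            for b in iterative_synteny(records, MergeSchedule((5, 20), 100)):
                for prev, cur in zip(b.members, b.members[1:]):
                    assert 0 <= cur.ref_start - prev.ref_end <= 100


class TestClassifyRearrangements:
    def test_collinear_no_calls(self):
        blocks = iterative_synteny(
            [rec(0, 60_000, 0, 60_000), rec(70_000, 130_000, 70_000, 130_000)],
            MergeSchedule((200,), 1_000))
        assert classify_rearrangements(blocks) == []

    def test_distant_duplication_called_with_overlap(self, rng):
        anc = random_chromosome("anc", 3_000_000, rng)
        tree = SimNode("root", children=[
            SimNode("ref"),
            SimNode("alt", subs_rate=0.02, events=[StructuralEvent(
                "duplication", 400_000, 500_000, insertion_point=2_500_000)])])
        tips = simulate_allele_histories(anc, tree, rng)
        recs = emit_truth_alignments(tips["ref"], tips["alt"], 200)
        calls = classify_rearrangements(iterative_synteny(recs))
        dups = [c for c in calls if c.kind == "duplication"]
        assert len(dups) == 1
        ov = (min(dups[0].ref_end, 500_000) - max(dups[0].ref_start, 400_000))
        assert ov >= 0.9 * 100_000

    def test_inversion_bordered_by_duplicated_fragments(self, rng):
        """Duplication of a fragment to the far inversion boundary followed
        by the inversion itself: the inversion is recovered and a
        duplication is flagged at its border."""
        anc = random_chromosome("anc", 1_000_000, rng)
        tree = SimNode("root", children=[
            SimNode("ref"),
            SimNode("alt", subs_rate=0.02, events=[
                StructuralEvent("duplication", 290_000, 360_000,
                                insertion_point=640_000, orientation="-"),
                StructuralEvent("inversion", 360_000, 640_000)])])
        tips = simulate_allele_histories(anc, tree, rng)
        calls = classify_rearrangements(iterative_synteny(
            emit_truth_alignments(tips["ref"], tips["alt"], 200)))
        kinds = {c.kind for c in calls}
        assert "inversion" in kinds and "duplication" in kinds
        inv = [c for c in calls if c.kind == "inversion"]
        assert any(c.ref_start < 640_000 and c.ref_end > 360_000 for c in inv)
        dup = [c for c in calls if c.kind == "duplication"]
        assert any(c.ref_start < 360_000 and c.ref_end > 290_000 for c in dup)

    def test_translocation_rank_disagreement(self):
        blocks = iterative_synteny(
            [rec(0, 50_000, 100_000, 150_000),
             rec(60_000, 110_000, 160_000, 210_000),
             rec(120_000, 170_000, 0, 50_000)],
            MergeSchedule((200,), 1_000))
        calls = classify_rearrangements(blocks)
        assert [c.kind for c in calls] == ["translocation"]
        assert calls[0].ref_start == 120_000
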
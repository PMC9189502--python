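"""Synteny-block inference from pairwise whole-chromosome alignments.

The block-building algorithm proceeds in three steps that can be applied
iteratively: (1) alignments are split into *sub-blocks*, each covering a
unique tract of the reference (the reference axis is segmented at every
alignment boundary, so overlapping alignments yield distinct sub-blocks
over the shared tract); (2) sub-blocks below a minimum reference span are
discarded; (3) surviving sub-blocks that are adjacent in the reference,
co-oriented and within a maximum gap are chained into synteny blocks.
Each iteration feeds the previous iteration's blocks back in with a
larger minimum size, building fine-scale synteny up into large blocks
(default schedule: 200 bp, 2 kb, 20 kb minima with a 100 kb gap).

Rearrangements are then read off the final blocks: runs of minus-strand
blocks are inversions, reference tracts claimed by two or more blocks
with distinct query tracts are duplications, and blocks whose query-side
rank disagrees with their reference rank are translocations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paf import AlignmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SubBlock", "SyntenyBlock", "MergeSchedule", "RearrangementCall",
    "DEFAULT_SCHEDULE", "filter_alignments", "split_subblocks",
    "merge_blocks", "iterative_synteny", "classify_rearrangements",
    "blocks_to_frame", "write_blocks_tsv", "write_blocks_bed9",
]


@dataclass(frozen=True)
class SubBlock:
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    parent: int = -1    # index of the parent alignment/block in the input

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SyntenyBlock:
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    level: int = 1
    members: list[SubBlock] = field(default_factory=list)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class MergeSchedule:
    """Per-iteration minimum sub-block sizes and maximum chaining gap."""

    min_sizes: tuple[int, ...] = (200, 2_000, 20_000)
    max_distance: int = 100_000

    def __post_init__(self):
        if not self.min_sizes or any(s <= 0 for s in self.min_sizes):
            raise ValueError("min_sizes must be positive")
        if any(b <= a for a, b in zip(self.min_sizes, self.min_sizes[1:])):
            raise ValueError("min_sizes must be strictly increasing")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")

    @property
    def n_iterations(self) -> int:
        return len(self.min_sizes)


DEFAULT_SCHEDULE = MergeSchedule()


@dataclass(frozen=True)
class RearrangementCall:
    kind: str                                  # inversion | duplication | translocation
    ref_start: int
    ref_end: int
    query_name: str
    query_intervals: tuple[tuple[int, int], ...]
    blocks: tuple[int, ...]                    # indices into the final block list


def filter_alignments(records: Iterable[AlignmentRecord], min_length: int = 0,
                      max_dv: float | None = None,
                      keep_low_dv: bool = False) -> list[AlignmentRecord]:
    """Length/divergence filter, order-preserving.

    ``max_dv`` keeps records with dv ≤ max_dv; records lacking a dv tag
    are dropped with a warning when the filter is active. ``keep_low_dv``
    flips the direction (keep dv < max_dv, discard the rest), exposing
    the literal published wording for comparison.
    """
    out = []
    for r in records:
        if r.aligned_length < min_length:
            continue
        if max_dv is not None:
            if r.dv is None:
                logger.warning("dropping %s:%d-%d: dv filter active but "
                               "record has no dv tag", r.ref_name,
                               r.ref_start, r.ref_end)
                continue
            if keep_low_dv:
                if r.dv >= max_dv:
                    continue
            elif r.dv > max_dv:
                continue
        out.append(r)
    return out


def split_subblocks(records: Sequence[AlignmentRecord]) -> list[SubBlock]:
    """Segment the reference axis at every alignment boundary.

    Every (segment × covering alignment) pair becomes one sub-block whose
    query interval is obtained by strand-aware proportional interpolation
    within the parent alignment. All records must share one reference
    sequence.
    """
    records = list(records)
    if not records:
        return []
    ref_names = {r.ref_name for r in records}
    if len(ref_names) > 1:
        raise ValueError(f"records span multiple references: {sorted(ref_names)}")

    cuts = np.unique(np.concatenate(
        [[r.ref_start, r.ref_end] for r in records]))
    out: list[SubBlock] = []
    for idx, r in enumerate(records):
        inner = cuts[(cuts > r.ref_start) & (cuts < r.ref_end)]
        bounds = np.concatenate([[r.ref_start], inner, [r.ref_end]])
        scale = (r.query_end - r.query_start) / (r.ref_end - r.ref_start)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if r.strand == "+":
                qa = r.query_start + round((a - r.ref_start) * scale)
                qb = r.query_start + round((b - r.ref_start) * scale)
            else:
                qa = r.query_start + round((r.ref_end - b) * scale)
                qb = r.query_start + round((r.ref_end - a) * scale)
            if qb <= qa:
                qb = qa + 1   # rounding collapse on query-short alignments
            out.append(SubBlock(int(a), int(b), r.query_name, int(qa), int(qb),
                                r.strand, parent=idx))
    out.sort(key=_subblock_key)
    return out


def _subblock_key(sb: SubBlock):
    return (sb.ref_start, sb.ref_end, sb.query_name, sb.query_start, sb.strand)


def _query_gap(last: SubBlock, sb: SubBlock) -> int:
    if sb.strand == "+":
        return sb.query_start - last.query_end
    return last.query_start - sb.query_end


def merge_blocks(subblocks: Iterable[SubBlock], min_size: int,
                 max_distance: int, *, require_same_query: bool = True,
                 max_query_gap: int | str | None = "ref",
                 level: int = 1) -> list[SyntenyBlock]:
    """Discard small sub-blocks, then chain co-oriented neighbours.

    Sub-blocks are scanned in reference order; each joins the open chain
    with the same strand (and, by default, query name) whose last member
    ends at most ``max_distance`` before it — choosing, among candidates,
    the chain with the smallest forward query-side gap, so the two copies
    of a duplicated tract extend their own chains rather than swapping.
    The query-side gap must advance with the strand and is bounded by
    ``max_query_gap`` (default: the same ``max_distance`` as the
    reference gap; pass ``None`` for the literal reference-only rule —
    unbounded chains can fuse an inverted duplicate with a distant true
    inversion into one block). Overlapping sub-blocks never share a
    chain.
    """
    if max_query_gap == "ref":
        max_query_gap = max_distance
    survivors = sorted((sb for sb in subblocks if sb.ref_span >= min_size),
                       key=_subblock_key)
    chains: list[list[SubBlock]] = []
    open_chains: list[int] = []
    for sb in survivors:
        open_chains = [ci for ci in open_chains
                       if sb.ref_start - chains[ci][-1].ref_end <= max_distance]
        best, best_key = None, None
        for ci in open_chains:
            last = chains[ci][-1]
            if last.strand != sb.strand:
                continue
            if require_same_query and last.query_name != sb.query_name:
                continue
            rgap = sb.ref_start - last.ref_end
            if rgap < 0:
                continue
            if last.query_name == sb.query_name:
                qgap = _query_gap(last, sb)
                if qgap < 0:
                    continue    # query order must advance with the strand
                if max_query_gap is not None and qgap > max_query_gap:
                    continue
            else:
                # reachable only with require_same_query=False; the query
                # axes are incommensurable, so only the reference gap counts
                qgap = max_query_gap if max_query_gap is not None else 2**40
            key = (qgap, rgap, ci)
            if best_key is None or key < best_key:
                best, best_key = ci, key
        if best is None:
            chains.append([sb])
            open_chains.append(len(chains) - 1)
        else:
            chains[best].append(sb)

    blocks = []
    for members in chains:
        qname = members[0].query_name
        blocks.append(SyntenyBlock(
            ref_start=members[0].ref_start,
            ref_end=max(m.ref_end for m in members),
            query_name=qname,
            query_start=min(m.query_start for m in members),
            query_end=max(m.query_end for m in members),
            strand=members[0].strand,
            level=level,
            members=members,
        ))
    blocks.sort(key=lambda b: (b.ref_start, b.ref_end, b.query_name,
                               b.query_start, b.strand))
    return blocks


def _blocks_as_records(blocks: Sequence[SyntenyBlock], ref_name: str,
                       ) -> list[AlignmentRecord]:
    return [AlignmentRecord(
        ref_name=ref_name, ref_start=b.ref_start, ref_end=b.ref_end,
        query_name=b.query_name, query_start=b.query_start,
        query_end=b.query_end, strand=b.strand) for b in blocks]


def iterative_synteny(records: Sequence[AlignmentRecord],
                      schedule: MergeSchedule = DEFAULT_SCHEDULE, *,
                      require_same_query: bool = True,
                      max_query_gap: int | str | None = "auto") -> list[SyntenyBlock]:
    """Run split → size-filter → merge for every scheduled iteration.

    Iteration 1 consumes the raw alignments; each later iteration re-splits
    the previous blocks and merges with the next (larger) minimum size.
    A one-iteration schedule is exactly ``merge_blocks(split_subblocks(r))``.

    The reference-side chaining gap (``schedule.max_distance``) tolerates
    material deleted from the query; the query-side gap tolerates material
    inserted into it and defaults to the schedule's final minimum block
    size — an insertion large enough to matter at the calling resolution
    should start its own block, and letting chains skip further than that
    fuses inverted duplicates into genuine inversions. Pass an integer to
    override, or None for the literal reference-gap-only rule.
    """
    if max_query_gap == "auto":
        max_query_gap = schedule.min_sizes[-1]
    records = list(records)
    if not records:
        return []
    ref_name = records[0].ref_name
    blocks: list[SyntenyBlock] = []
    for it, min_size in enumerate(schedule.min_sizes, start=1):
        if it > 1:
            records = _blocks_as_records(blocks, ref_name)
        subs = split_subblocks(records)
        blocks = merge_blocks(subs, min_size, schedule.max_distance,
                              require_same_query=require_same_query,
                              max_query_gap=max_query_gap, level=it)
    return blocks


def _longest_increasing(seq: list[int]) -> set[int]:
    """Indices of one longest strictly increasing subsequence (O(n²);
    block counts are small). Earlier elements win ties, so output is
    deterministic."""
    n = len(seq)
    if n == 0:
        return set()
    length = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                prev[i] = j
    best = max(range(n), key=lambda i: (length[i], -i))
    keep = set()
    while best != -1:
        keep.add(best)
        best = prev[best]
    return keep


def _query_span_over(block: SyntenyBlock, s: int, e: int) -> tuple[int, int]:
    """Query tract of a block restricted to the ref interval [s, e).

    Uses the member sub-blocks when present, falling back to linear
    interpolation over the block span.
    """
    hits = [m for m in block.members
            if m.ref_start < e and m.ref_end > s]
    if hits:
        return (min(m.query_start for m in hits),
                max(m.query_end for m in hits))
    scale = (block.query_end - block.query_start) / block.ref_span
    if block.strand == "+":
        return (block.query_start + round((s - block.ref_start) * scale),
                block.query_start + round((e - block.ref_start) * scale))
    return (block.query_start + round((block.ref_end - e) * scale),
            block.query_start + round((block.ref_end - s) * scale))


def _split_at_query_jumps(blocks: Sequence[SyntenyBlock],
                          max_jump: int) -> list[SyntenyBlock]:
    """Re-segment blocks whose members jump more than ``max_jump`` on the
    query axis: such a jump means unrelated material was chained across
    (the default chaining rule bounds only the reference gap), and calling
    on the unsplit block would fuse distinct rearrangements."""
    out: list[SyntenyBlock] = []
    for b in blocks:
        if len(b.members) < 2:
            out.append(b)
            continue
        groups: list[list[SubBlock]] = [[b.members[0]]]
        for prev, cur in zip(b.members, b.members[1:]):
            gap = _query_gap(prev, cur)
            if gap > max_jump:
                groups.append([cur])
            else:
                groups[-1].append(cur)
        if len(groups) == 1:
            out.append(b)
            continue
        for g in groups:
            out.append(SyntenyBlock(
                ref_start=g[0].ref_start,
                ref_end=max(m.ref_end for m in g),
                query_name=g[0].query_name,
                query_start=min(m.query_start for m in g),
                query_end=max(m.query_end for m in g),
                strand=b.strand, level=b.level, members=g))
    return out


def classify_rearrangements(blocks: Sequence[SyntenyBlock],
                            min_dup_overlap: float = 0.5,
                            max_run_gap: int = 20_000,
                            ) -> list[RearrangementCall]:
    """Call inversions, duplications and translocations from final blocks.

    * inversion: maximal run of minus-strand blocks in reference order,
      query-collinear and with ref/query gaps ≤ ``max_run_gap`` (default:
      the final-iteration minimum block size, since a larger gap implies
      structure that would have survived as its own block);
    * duplication: reference tract claimed by ≥2 blocks whose query
      tracts are distinct (reciprocal query overlap < ``min_dup_overlap``);
    * translocation: among the remaining plus-strand single-copy blocks,
      a block whose query-order rank differs from its reference-order rank.
    """
    blocks = _split_at_query_jumps(blocks, max_run_gap)
    blocks = sorted(blocks, key=lambda b: (b.ref_start, b.ref_end,
                                           b.query_name, b.query_start))
    calls: list[RearrangementCall] = []

    # --- inversions: query-collinear runs of '-' blocks (along an
    # inverted tract the query coordinate must FALL as the ref advances;
    # a jump back up means an unrelated inverted tract, e.g. a second
    # inversion or an inverted duplicate, and starts a new call)
    i = 0
    inv_members: set[int] = set()
    while i < len(blocks):
        if blocks[i].strand == "-":
            j = i
            while (j + 1 < len(blocks) and blocks[j + 1].strand == "-"
                   and blocks[j + 1].query_name == blocks[j].query_name
                   and blocks[j + 1].query_start < blocks[j].query_start
                   and blocks[j + 1].ref_start - blocks[j].ref_end
                   <= max_run_gap
                   and blocks[j].query_start - blocks[j + 1].query_end
                   <= max_run_gap):
                j += 1
            run = list(range(i, j + 1))
            inv_members.update(run)
            calls.append(RearrangementCall(
                kind="inversion",
                ref_start=min(blocks[k].ref_start for k in run),
                ref_end=max(blocks[k].ref_end for k in run),
                query_name=blocks[i].query_name,
                query_intervals=tuple((blocks[k].query_start, blocks[k].query_end)
                                      for k in run),
                blocks=tuple(run),
            ))
            i = j + 1
        else:
            i += 1

    # --- duplications: ref-overlapping block pairs with distinct query tracts
    dup_members: set[int] = set()
    dup_regions: list[tuple[int, int, tuple[int, ...]]] = []
    for a in range(len(blocks)):
        for b in range(a + 1, len(blocks)):
            if blocks[b].ref_start >= blocks[a].ref_end:
                break
            s = max(blocks[a].ref_start, blocks[b].ref_start)
            e = min(blocks[a].ref_end, blocks[b].ref_end)
            if e <= s:
                continue
            if blocks[a].query_name == blocks[b].query_name:
                qa = _query_span_over(blocks[a], s, e)
                qb = _query_span_over(blocks[b], s, e)
                ov_q = min(qa[1], qb[1]) - max(qa[0], qb[0])
                smaller = min(qa[1] - qa[0], qb[1] - qb[0])
                if smaller > 0 and ov_q > min_dup_overlap * smaller:
                    continue      # same query tract seen twice, not a duplication
            dup_regions.append((s, e, (a, b)))
            dup_members.update((a, b))
    # merge overlapping duplication regions into single calls
    dup_regions.sort()
    merged: list[list] = []
    for s, e, pair in dup_regions:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].update(pair)
        else:
            merged.append([s, e, set(pair)])
    for s, e, members in merged:
        mem = tuple(sorted(members))
        calls.append(RearrangementCall(
            kind="duplication", ref_start=int(s), ref_end=int(e),
            query_name=blocks[mem[0]].query_name,
            query_intervals=tuple((blocks[k].query_start, blocks[k].query_end)
                                  for k in mem),
            blocks=mem,
        ))

    # --- translocations: blocks breaking query-order collinearity among
    # the remaining blocks. The minimal such set (complement of a longest
    # increasing subsequence of query ranks) is called, so one moved block
    # yields one call rather than cascading rank shifts.
    rest = [k for k in range(len(blocks))
            if k not in inv_members and k not in dup_members]
    by_query = sorted(rest, key=lambda k: (blocks[k].query_name,
                                           blocks[k].query_start))
    qrank = {k: r for r, k in enumerate(by_query)}
    seq = [qrank[k] for k in rest]        # rest is already in ref order
    keep = _longest_increasing(seq)
    for pos, k in enumerate(rest):
        if pos not in keep:
            b = blocks[k]
            calls.append(RearrangementCall(
                kind="translocation", ref_start=b.ref_start, ref_end=b.ref_end,
                query_name=b.query_name,
                query_intervals=((b.query_start, b.query_end),),
                blocks=(k,),
            ))
    calls.sort(key=lambda c: (c.ref_start, c.ref_end, c.kind))
    return calls


def blocks_to_frame(blocks: Sequence[SyntenyBlock], ref_name: str = "ref",
                    ) -> pd.DataFrame:
    return pd.DataFrame({
        "ref_name": ref_name,
        "ref_start": [b.ref_start for b in blocks],
        "ref_end": [b.ref_end for b in blocks],
        "query_name": [b.query_name for b in blocks],
        "query_start": [b.query_start for b in blocks],
        "query_end": [b.query_end for b in blocks],
        "strand": [b.strand for b in blocks],
        "level": [b.level for b in blocks],
    })


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path: str | Path,
                     ref_name: str = "ref") -> None:
    blocks_to_frame(blocks, ref_name).to_csv(path, sep="\t", index=False)


def write_blocks_bed9(blocks: Sequence[SyntenyBlock], path: str | Path,
                      ref_name: str = "ref",
                      forward_rgb: str = "49,130,189",
                      reverse_rgb: str = "222,45,38") -> None:
    """BED9 track with minus-strand blocks coloured distinctly."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            rgb = forward_rgb if b.strand == "+" else reverse_rgb
            fh.write("\t".join(map(str, [
                ref_name, b.ref_start, b.ref_end,
                f"{b.query_name}:{b.query_start}-{b.query_end}",
                0, b.strand, b.ref_start, b.ref_end, rgb])) + "\n")
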
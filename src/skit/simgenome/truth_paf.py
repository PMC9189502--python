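"""Ground-truth alignment emission from coordinate maps.

Two haplotypes descended from one ancestor are "aligned" exactly by
matching their per-base provenance: maximal co-linear, co-oriented runs of
shared ancestry become alignment records, replacing an external aligner
for simulated data. The per-record ``dv`` is the realized per-base
mismatch fraction, so downstream divergence filters see honest values.
"""

from __future__ import annotations

import numpy as np

from .._seq import complement
from ..paf import AlignmentRecord
from .haplotype import Haplotype, NOVEL


def emit_truth_alignments(ref: Haplotype, query: Haplotype,
                          min_segment: int = 1) -> list[AlignmentRecord]:
    """Emit maximal shared-ancestry runs ≥ ``min_segment`` bp as records.

    A run pairs consecutive query bases with consecutive ref bases of the
    same ancestral origin; its strand is the product of the two maps'
    orientations. Duplications naturally produce multiple records over one
    ancestral tract; novel bases align nowhere.
    """
    r_anc = ref.cmap.anc
    q_anc = query.cmap.anc

    order = np.argsort(r_anc, kind="stable")
    r_sorted = r_anc[order]
    # candidate pairs (i on query, j on ref) sharing an ancestral base
    valid_q = np.flatnonzero(q_anc != NOVEL)
    lo = np.searchsorted(r_sorted, q_anc[valid_q], side="left")
    hi = np.searchsorted(r_sorted, q_anc[valid_q], side="right")
    counts = hi - lo
    keep = counts > 0
    valid_q, lo, counts = valid_q[keep], lo[keep], counts[keep]
    if len(valid_q) == 0:
        return []
    i_idx = np.repeat(valid_q, counts)
    total = int(counts.sum())
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    j_idx = order[np.repeat(lo, counts) + offsets]

    same_sense = ref.cmap.orient[j_idx] == query.cmap.orient[i_idx]

    records: list[AlignmentRecord] = []
    for sense in (True, False):
        sel = same_sense == sense
        ii, jj = i_idx[sel], j_idx[sel]
        if len(ii) == 0:
            continue
        diag = jj - ii if sense else jj + ii
        srt = np.lexsort((ii, diag))
        ii, jj, diag = ii[srt], jj[srt], diag[srt]
        brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(ii) != 1))
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk + 1, [len(ii)]])
        for s, e in zip(starts, ends):
            if e - s < min_segment:
                continue
            qi = ii[s:e]
            rj = jj[s:e]
            qb = query.codes[qi]
            rb = ref.codes[rj] if sense else complement(ref.codes[rj])
            mism = int(np.count_nonzero(qb != rb))
            n = e - s
            records.append(AlignmentRecord(
                ref_name=ref.name,
                ref_start=int(rj.min()), ref_end=int(rj.max()) + 1,
                query_name=query.name,
                query_start=int(qi[0]), query_end=int(qi[-1]) + 1,
                strand="+" if sense else "-",
                ref_len=len(ref), query_len=len(query),
                n_matches=n - mism, aligned_length=n,
                dv=mism / n,
            ))
    records.sort(key=lambda r: (r.ref_start, r.ref_end, r.query_start))
    return records
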
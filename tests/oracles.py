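"""Independent brute-force reference implementations used by the tests.

Everything here favours obviousness over speed: per-base segmentation,
all-pairs statistics, exhaustive translation. These functions never call
the library code paths they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# synteny: per-base segmentation + O(n^2) chain building


def oracle_split(records):
    """(ref interval × covering alignment) sub-blocks via per-base scan.

    Returns tuples (ref_start, ref_end, query_name, query_start,
    query_end, strand, parent_idx) sorted like the library.
    """
    if not records:
        return []
    lo = min(r.ref_start for r in records)
    hi = max(r.ref_end for r in records)
    # covering set per base
    cover = [frozenset(i for i, r in enumerate(records)
                       if r.ref_start <= p < r.ref_end)
             for p in range(lo, hi)]
    out = []
    for idx, r in enumerate(records):
        # maximal runs of constant covering set within this record
        p = r.ref_start
        while p < r.ref_end:
            q = p
            while q + 1 < r.ref_end and cover[q + 1 - lo] == cover[p - lo]:
                q += 1
            a, b = p, q + 1
            scale = (r.query_end - r.query_start) / (r.ref_end - r.ref_start)
            if r.strand == "+":
                qa = r.query_start + round((a - r.ref_start) * scale)
                qb = r.query_start + round((b - r.ref_start) * scale)
            else:
                qa = r.query_start + round((r.ref_end - b) * scale)
                qb = r.query_start + round((r.ref_end - a) * scale)
            if qb <= qa:
                qb = qa + 1
            out.append((a, b, r.query_name, int(qa), int(qb), r.strand, idx))
            p = b
    out.sort(key=lambda s: (s[0], s[1], s[2], s[3], s[5]))
    return out


def oracle_merge(subs, min_size, max_distance, max_query_gap=None,
                 require_same_query=True):
    """Chain building by exhaustive candidate scan (O(n^2)).

    Join rule: same strand (and query name), non-negative reference gap
    ≤ max_distance, query coordinate advancing with the strand by at most
    max_query_gap (None = unbounded); the candidate chain minimising
    (query gap, ref gap, chain index) wins.
    """
    subs = sorted((s for s in subs if s[1] - s[0] >= min_size),
                  key=lambda s: (s[0], s[1], s[2], s[3], s[5]))
    chains = []
    for s in subs:
        best = None
        for ci, chain in enumerate(chains):
            last = chain[-1]
            if last[5] != s[5]:
                continue
            if require_same_query and last[2] != s[2]:
                continue
            rgap = s[0] - last[1]
            if rgap < 0 or rgap > max_distance:
                continue
            qgap = s[3] - last[4] if s[5] == "+" else last[3] - s[4]
            if qgap < 0:
                continue
            if max_query_gap is not None and qgap > max_query_gap:
                continue
            cand = (qgap, rgap, ci)
            if best is None or cand < best:
                best = cand
        if best is None:
            chains.append([s])
        else:
            chains[best[2]].append(s)
    blocks = []
    for chain in chains:
        blocks.append((
            chain[0][0], max(c[1] for c in chain), chain[0][2],
            min(c[3] for c in chain), max(c[4] for c in chain), chain[0][5]))
    blocks.sort(key=lambda b: (b[0], b[1], b[2], b[3], b[5]))
    return blocks


def oracle_iterative(records, min_sizes, max_distance, max_query_gap=None):
    """Reference for the full iterative pipeline on small instances."""
    if max_query_gap is None:
        max_query_gap = min_sizes[-1]
    from skit.paf import AlignmentRecord   # only to re-wrap intervals

    recs = list(records)
    blocks = None
    for it, min_size in enumerate(min_sizes, start=1):
        if it > 1:
            recs = [AlignmentRecord(ref_name=records[0].ref_name,
                                    ref_start=b[0], ref_end=b[1],
                                    query_name=b[2], query_start=b[3],
                                    query_end=b[4], strand=b[5])
                    for b in blocks]
        subs = oracle_split(recs)
        blocks = oracle_merge(subs, min_size, max_distance,
                              max_query_gap=max_query_gap)
    return blocks


# ---------------------------------------------------------------------------
# population statistics: all-pairs loops


def oracle_pi(alleles):
    """Mean pairwise difference across all allele pairs, site by site."""
    vals = []
    for site in alleles:
        obs = [a for a in site if a >= 0]
        if len(obs) < 2:
            continue
        pairs = list(combinations(obs, 2))
        vals.append(sum(a != b for a, b in pairs) / len(pairs))
    return float(np.mean(vals)) if vals else float("nan")


def oracle_dxy(alleles_a, alleles_b):
    vals = []
    for sa, sb in zip(alleles_a, alleles_b):
        oa = [a for a in sa if a >= 0]
        ob = [b for b in sb if b >= 0]
        if not oa or not ob:
            continue
        vals.append(sum(a != b for a in oa for b in ob) / (len(oa) * len(ob)))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# fourfold degeneracy: exhaustive translation of all four substitutions


def oracle_fourfold(cds):
    from Bio.Seq import Seq

    mask = [False] * len(cds)
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if any(c not in "ACGT" for c in codon[:2]):
            continue
        aas = {str(Seq(codon[:2] + n).translate()) for n in "ACGT"}
        mask[i + 2] = len(aas) == 1
    return np.array(mask)
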
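"""Per-gene CDS alignments from genotype calls, and a distance tree.

Alignments are built by masking low-quality genotypes, dropping every
site that is missing in *any* sample, collapsing diploid calls to single
IUPAC bases, and splicing CDS coordinates strand-aware — reference
positions that fell out of the call set come back as N, so the N-count
filters measure how much of each gene actually survived. Filtered gene
sets can be concatenated (with a partition table) and summarized with a
neighbour-joining tree on IUPAC-aware p-distances — a light-weight
topology check for simulated data, not a substitute for likelihood-based
phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ._seq import IUPAC_TO_BASES, MISSING, iupac_from_pair, revcomp_str
from .genotypes import GenotypeMatrix
from .simgenome.chromosome import GeneModel

__all__ = ["GeneAlignment", "extract_gene_alignments",
           "filter_gene_alignments", "concatenate", "p_distance_matrix",
           "nj_tree", "write_fasta"]


@dataclass
class GeneAlignment:
    gene_id: str
    samples: list[str]
    seqs: list[str]         # equal lengths; {ACGT, IUPAC, N}

    def __post_init__(self):
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError(f"unequal sequence lengths in {self.gene_id}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def n_counts(self) -> dict[str, int]:
        return {s: seq.count("N") for s, seq in zip(self.samples, self.seqs)}


def _mask_low_quality(mat: GenotypeMatrix, min_gq: int, min_dp: int,
                      combine: str) -> GenotypeMatrix:
    """Set calls failing the GQ/DP rule to missing.

    ``combine='or'`` fails a call that misses either threshold (the
    default); ``'and'`` only fails calls missing both, the literal
    published wording.
    """
    if min_gq <= 0 and min_dp <= 0:
        return mat
    if mat.gq is None or mat.dp is None:
        raise ValueError("GQ/DP filtering requires annotated matrices")
    low_gq = mat.gq < min_gq
    low_dp = mat.dp < min_dp
    fail = (low_gq | low_dp) if combine == "or" else (low_gq & low_dp)
    gt = mat.gt.copy()
    gt[fail] = MISSING
    return GenotypeMatrix(chrom=mat.chrom, pos=mat.pos, samples=list(mat.samples),
                          gt=gt, target_name=mat.target_name, target=mat.target,
                          dp=mat.dp, gq=mat.gq)


def extract_gene_alignments(mat: GenotypeMatrix, genes: Sequence[GeneModel],
                            chrom: str | None = None, *,
                            min_gq: int = 20, min_dp: int = 5,
                            combine: str = "or",
                            include_target: bool = False,
                            ) -> dict[str, GeneAlignment]:
    """Build one IUPAC alignment per gene from a genotype matrix.

    Processing order matters and is fixed: (1) genotypes failing the
    GQ/DP rule become missing; (2) sites missing in any sample are
    removed; (3) surviving diploid calls collapse to IUPAC single bases;
    (4) each gene's CDS is spliced from its exons, reverse-complemented
    for minus-strand genes; positions absent after step 2 (or never
    called) are filled with N.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    mat = _mask_low_quality(mat, min_gq, min_dp, combine)
    if chrom is not None:
        mat = mat.take_sites(mat.chrom == chrom)

    complete = ~(mat.gt[:, :, 0] == MISSING).any(axis=1)
    if include_target:
        if mat.target is None:
            raise ValueError("include_target requires a target column")
        complete &= mat.target != MISSING
    kept = mat.take_sites(complete)

    sample_names = list(kept.samples) + (
        [kept.target_name] if include_target else [])
    pos_index = {int(p): i for i, p in enumerate(kept.pos)}

    out: dict[str, GeneAlignment] = {}
    for g in genes:
        cds_pos = g.cds_positions()   # already in translation order
        cols = []
        for p in cds_pos:
            i = pos_index.get(int(p))
            if i is None:
                cols.append(["N"] * len(sample_names))
                continue
            col = [iupac_from_pair(int(a), int(b)) for a, b in kept.gt[i]]
            if include_target:
                col.append("ACGT"[kept.target[i]])
            cols.append(col)
        if g.strand == "-":
            # cds_positions already runs 3'→5' on the forward strand;
            # complement each base to get the coding sequence
            seqs = ["".join(revcomp_str(c)[0] for c in col)
                    for col in zip(*cols)] if cols else [""] * len(sample_names)
        else:
            seqs = ["".join(col) for col in zip(*cols)] if cols else \
                [""] * len(sample_names)
        out[g.gene_id] = GeneAlignment(g.gene_id, list(sample_names), seqs)
    return out


def filter_gene_alignments(alignments: dict[str, GeneAlignment],
                           max_n: int = 500, max_n_frac: float = 0.75,
                           ) -> dict[str, GeneAlignment]:
    """Drop genes where any sample has more than ``max_n`` Ns or an
    N-fraction of at least ``max_n_frac`` (inclusive)."""
    out = {}
    for gid, aln in alignments.items():
        length = aln.length
        counts = aln.n_counts().values()
        if any(c > max_n for c in counts):
            continue
        if length and any(c / length >= max_n_frac for c in counts):
            continue
        if length == 0:
            continue
        out[gid] = aln
    return out


def concatenate(alignments: dict[str, GeneAlignment],
                gene_order: Sequence[str] | None = None,
                ) -> tuple[GeneAlignment, list[tuple[str, int, int]]]:
    """Join gene alignments end to end; returns the supermatrix and a
    partition table of (gene, start, end) half-open offsets."""
    order = list(gene_order) if gene_order is not None else list(alignments)
    if not order:
        raise ValueError("empty gene subset")
    missing = [g for g in order if g not in alignments]
    if missing:
        raise KeyError(f"genes not in the alignment set: {missing}")
    samples = alignments[order[0]].samples
    for g in order[1:]:
        if alignments[g].samples != samples:
            raise ValueError(f"sample set of {g} differs")
    parts, offset = [], 0
    chunks = {s: [] for s in samples}
    for g in order:
        aln = alignments[g]
        for s, seq in zip(aln.samples, aln.seqs):
            chunks[s].append(seq)
        parts.append((g, offset, offset + aln.length))
        offset += aln.length
    combined = GeneAlignment("concat", list(samples),
                             ["".join(chunks[s]) for s in samples])
    return combined, parts


_SETS = {k: frozenset(v) for k, v in IUPAC_TO_BASES.items()}


def _pair_mismatch(a: str, b: str) -> float | None:
    """Expected mismatch between two IUPAC characters; None if either is N."""
    if a == "N" or b == "N":
        return None
    sa, sb = _SETS[a], _SETS[b]
    shared = len(sa & sb)
    return 1.0 - shared / (len(sa) * len(sb))


def p_distance_matrix(aln: GeneAlignment) -> DistanceMatrix:
    """Pairwise p-distances with ambiguity codes contributing their
    expected mismatch (e.g. R vs A = 0.5); N is excluded pairwise."""
    n = len(aln.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = mism = 0.0
            for a, b in zip(aln.seqs[i], aln.seqs[j]):
                m = _pair_mismatch(a, b)
                if m is None:
                    continue
                tot += 1
                mism += m
            d[i, j] = d[j, i] = mism / tot if tot else 0.0
    return DistanceMatrix(d, ids=aln.samples)


def nj_tree(aln: GeneAlignment):
    """Neighbour-joining tree on p-distances; needs ≥3 samples.

    Negative branch-length estimates are clamped to zero (the scikit-bio
    default). Returns a ``skbio.TreeNode``; use ``str(tree)`` or
    ``tree.write`` for Newick.
    """
    if len(aln.samples) < 3:
        raise ValueError("neighbour joining needs at least 3 samples")
    return nj(p_distance_matrix(aln))


def write_fasta(aln: GeneAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, seq in zip(aln.samples, aln.seqs):
            fh.write(f">{s}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
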
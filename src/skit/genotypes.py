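"""Diploid genotype matrices with an optional haploid target column.

The matrix is the in-memory form of a multi-sample call set that includes
invariant sites: positions × individuals, two allele codes per call
(0..3 = A,C,G,T; -1 = missing, always jointly for both alleles of a
call). Per-call DP and GQ are carried when the source provides them.
Sources: an all-sites VCF, or the simpler two-allele "geno" TSV
(CHROM, POS, then one "A/T"-style column per sample; "N/N" = missing;
a haploid column holds a single base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES, MISSING, _CODE

__all__ = ["GenotypeMatrix", "read_geno_tsv", "write_geno_tsv", "read_vcf"]


@dataclass
class GenotypeMatrix:
    chrom: np.ndarray            # (S,) sequence name per site
    pos: np.ndarray              # (S,) 0-based positions, increasing per chrom
    samples: list[str]
    gt: np.ndarray               # (S, N, 2) int8 allele codes, -1 missing
    target_name: str | None = None
    target: np.ndarray | None = None   # (S,) int8 haploid allele codes
    dp: np.ndarray | None = None       # (S, N) int32
    gq: np.ndarray | None = None       # (S, N) int32

    def __post_init__(self):
        S = len(self.pos)
        if self.gt.shape != (S, len(self.samples), 2):
            raise ValueError("gt shape does not match sites × samples × 2")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        one_missing = (self.gt == MISSING).sum(axis=2) == 1
        if one_missing.any():
            raise ValueError("half-missing diploid calls are not allowed")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, names) -> np.ndarray:
        idx = []
        for n in names:
            try:
                idx.append(self.samples.index(n))
            except ValueError:
                raise KeyError(f"sample {n!r} not in matrix") from None
        return np.asarray(idx, dtype=np.intp)

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        m = mask_or_idx
        return GenotypeMatrix(
            chrom=self.chrom[m], pos=self.pos[m], samples=list(self.samples),
            gt=self.gt[m], target_name=self.target_name,
            target=None if self.target is None else self.target[m],
            dp=None if self.dp is None else self.dp[m],
            gq=None if self.gq is None else self.gq[m],
        )

    def alleles_for(self, sample_names, include_target: bool = False) -> np.ndarray:
        """(S, 2k [+1]) allele-code array for the named diploid samples,
        with the haploid target appended as one extra column on request."""
        idx = self.sample_index(sample_names)
        alle = self.gt[:, idx, :].reshape(self.n_sites, -1)
        if include_target:
            if self.target is None:
                raise ValueError("matrix has no target column")
            alle = np.concatenate([alle, self.target[:, None]], axis=1)
        return alle


def _parse_call(tok: str) -> tuple[int, int]:
    if len(tok) == 1:  # haploid
        a = _CODE[ord(tok)]
        return (a, a)
    a, b = tok[0], tok[2]
    return (_CODE[ord(a)], _CODE[ord(b)])


def read_geno_tsv(path: str | Path, target: str | None = None) -> GenotypeMatrix:
    """Read a geno TSV; ``target`` names the column to treat as haploid."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["CHROM", "POS"]:
            raise ValueError("geno TSV must start with CHROM and POS columns")
        names = header[2:]
        chroms, poss, rows = [], [], []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0])
            poss.append(int(f[1]) - 1)
            rows.append([_parse_call(t) for t in f[2:]])
    gt = np.asarray(rows, dtype=np.int8)
    gt[(gt == MISSING).any(axis=2)] = MISSING
    tgt = None
    if target is not None:
        ti = names.index(target)
        tgt = gt[:, ti, 0].copy()
        keep = [i for i in range(len(names)) if i != ti]
        gt = gt[:, keep, :]
        names = [names[i] for i in keep]
    return GenotypeMatrix(
        chrom=np.asarray(chroms), pos=np.asarray(poss, dtype=np.int64),
        samples=names, gt=gt, target_name=target, target=tgt,
    )


def write_geno_tsv(mat: GenotypeMatrix, path: str | Path) -> None:
    cols = list(mat.samples) + ([mat.target_name] if mat.target is not None else [])
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\t" + "\t".join(cols) + "\n")
        for s in range(mat.n_sites):
            toks = []
            for j in range(len(mat.samples)):
                a, b = mat.gt[s, j]
                toks.append("N/N" if a == MISSING else f"{BASES[a]}/{BASES[b]}")
            if mat.target is not None:
                t = mat.target[s]
                toks.append("N" if t == MISSING else BASES[t])
            fh.write(f"{mat.chrom[s]}\t{mat.pos[s] + 1}\t" + "\t".join(toks) + "\n")


def read_vcf(path: str | Path, target: str | None = None,
             drop_indels: bool = True) -> GenotypeMatrix:
    """Read an all-sites VCF (invariant sites included) via cyvcf2.

    Multiallelic SNP sites are kept; genotypes are translated to base
    codes through each record's REF/ALT. ``target`` names the haploid
    assembly sample (its first allele is used).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    chroms, poss, gts, dps, gqs = [], [], [], [], []

    def _fmt(rec, key):
        try:
            v = rec.format(key)
        except KeyError:
            v = None
        if v is None:
            return np.full(len(names), -1, dtype=np.int32)
        return v[:, 0].astype(np.int32)

    for rec in vcf:
        alleles = [rec.REF] + list(rec.ALT)
        if drop_indels and any(len(a) != 1 for a in alleles):
            continue
        codes = np.array([_CODE[ord(a[0])] if a else MISSING for a in alleles],
                         dtype=np.int8)
        g = rec.genotype.array()[:, :2]
        site = np.where(g >= 0, codes[np.clip(g, 0, None)], MISSING).astype(np.int8)
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)
        gts.append(site)
        dps.append(_fmt(rec, "DP"))
        gqs.append(_fmt(rec, "GQ"))
    gt = np.stack(gts) if gts else np.empty((0, len(names), 2), dtype=np.int8)
    gt[(gt == MISSING).any(axis=2)] = MISSING
    dp = np.stack(dps) if dps else None
    gq = np.stack(gqs) if gqs else None
    if dp is not None and (dp < 0).all():
        dp = None
    if gq is not None and (gq < 0).all():
        gq = None
    mat = GenotypeMatrix(
        chrom=np.asarray(chroms), pos=np.asarray(poss, dtype=np.int64),
        samples=names, gt=gt, dp=dp, gq=gq,
    )
    if target is not None:
        ti = names.index(target)
        tgt = mat.gt[:, ti, 0].copy()
        keep = [i for i in range(len(names)) if i != ti]
        mat = GenotypeMatrix(
            chrom=mat.chrom, pos=mat.pos,
            samples=[names[i] for i in keep], gt=mat.gt[:, keep, :],
            target_name=target, target=tgt,
            dp=None if dp is None else dp[:, keep],
            gq=None if gq is None else gq[:, keep],
        )
    return mat
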
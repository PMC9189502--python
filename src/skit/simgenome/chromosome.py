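"""Ancestral chromosomes and gene models for simulation.

The ancestral chromosome stands in for a structurally unrearranged
outgroup assembly: downstream stages treat it as the reference against
which derived haplotypes are aligned and annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import BASES, decode


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered exon intervals on one strand.

    Exons are half-open intervals in chromosome coordinates, stored in
    ascending order regardless of strand; ``frame`` is the codon phase of
    the first CDS base (0 for complete models).
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    frame: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_positions(self) -> np.ndarray:
        """Chromosome positions of CDS bases in translation order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class AncestralChromosome:
    name: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty ancestral sequence")
        n = len(self.sequence)
        for g in self.genes:
            if g.start < 0 or g.end > n:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
            if g.cds_length % 3 != 0:
                raise ValueError(f"gene {g.gene_id} CDS length not a multiple of 3")

    def __len__(self) -> int:
        return len(self.sequence)


def random_chromosome(name: str, length: int, rng: np.random.Generator, *,
                      n_genes: int = 0, exons_per_gene: int = 1,
                      exon_length: int = 300, intron_length: int = 100,
                      seed: int | None = None) -> AncestralChromosome:
    """Draw a uniform-random chromosome with evenly spaced gene models.

    Genes are laid out left to right with alternating strands; exon length
    must be a multiple of 3 so every CDS is a whole number of codons.
    """
    if exon_length % 3 != 0:
        raise ValueError("exon_length must be a multiple of 3")
    codes = rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)
    seq = decode(codes)

    genes: list[GeneModel] = []
    if n_genes:
        span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length
        pitch = length // n_genes
        if span + 1 > pitch:
            raise ValueError("genes do not fit: reduce n_genes or exon sizes")
        for i in range(n_genes):
            g0 = i * pitch
            exons = tuple(
                (g0 + j * (exon_length + intron_length),
                 g0 + j * (exon_length + intron_length) + exon_length)
                for j in range(exons_per_gene)
            )
            genes.append(GeneModel(f"gene{i:04d}", exons, "+" if i % 2 == 0 else "-"))
    return AncestralChromosome(name=name, sequence=seq, genes=genes, seed=seed)


def write_gff3(genes: list[GeneModel], chrom: str, path) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{chrom}\tskit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            fh.write(f"{chrom}\tskit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{chrom}\tskit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                         f"{g.frame}\tParent={g.gene_id}.t1\n")


def write_bed6(genes: list[GeneModel], chrom: str, path) -> None:
    """Write gene spans as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


def read_gff3(path) -> dict[str, list[GeneModel]]:
    """Read CDS gene models from GFF3, keyed by chromosome.

    CDS features are grouped by their Parent (or ID) attribute; exon order
    and strand are taken from the file.
    """
    by_gene: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]) - 1, int(f[4]), f[6], f[8]
            gid = None
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                if k in ("Parent", "ID"):
                    gid = v
                    break
            if gid is None:
                gid = attrs
            gid = gid.removesuffix(".t1")
            rec = by_gene.setdefault((chrom, gid), {"strand": strand, "exons": []})
            rec["exons"].append((start, end))
    out: dict[str, list[GeneModel]] = {}
    for (chrom, gid), rec in by_gene.items():
        exons = tuple(sorted(rec["exons"]))
        out.setdefault(chrom, []).append(GeneModel(gid, exons, rec["strand"]))
    for chrom in out:
        out[chrom].sort(key=lambda g: g.start)
    return out
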
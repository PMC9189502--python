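"""Per-site read-depth simulation with known gene copy numbers.

Depth at an exonic site is drawn with mean (per-copy coverage × true copy
number of the overlying gene): Poisson by default, negative binomial when
an overdispersion parameter is given. Only exonic sites are emitted —
depth outside annotated exons never enters the copy-number estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromosome import GeneModel


@dataclass
class DepthSimSpec:
    """Conditions for a depth simulation.

    ``coverage``: mean depth per haploid genome copy. ``copy_number``
    maps species → {gene_id → true integer copies}. ``individuals`` maps
    species → number of sequenced individuals. ``overdispersion`` is the
    negative-binomial shape k (variance = μ + μ²/k); None means Poisson.
    """

    coverage: float
    copy_number: dict[str, dict[str, int]]
    individuals: dict[str, int]
    overdispersion: float | None = None

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for sp, genes in self.copy_number.items():
            for g, c in genes.items():
                if c < 0 or int(c) != c:
                    raise ValueError(f"copy number for {sp}/{g} must be a "
                                     "non-negative integer")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")


@dataclass
class DepthTable:
    """Sites × individuals depth with the individual→species map and truth."""

    depth: pd.DataFrame                    # columns: CHROM, POS, <individual...>
    species_of: dict[str, str]
    true_copies: dict[str, dict[str, int]]  # species → gene → copies

    @property
    def individuals(self) -> list[str]:
        return [c for c in self.depth.columns if c not in ("CHROM", "POS")]

    def to_tsv(self, path) -> None:
        out = self.depth.copy()
        out["POS"] = out["POS"] + 1   # 1-based on disk
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, species_of: dict[str, str]) -> "DepthTable":
        df = pd.read_csv(path, sep="\t")
        df["POS"] = df["POS"] - 1
        return cls(depth=df, species_of=dict(species_of), true_copies={})


def simulate_depths(spec: DepthSimSpec, genes: list[GeneModel],
                    rng: np.random.Generator | int | None = None,
                    chrom: str = "chr1") -> DepthTable:
    """Draw per-site depths over the exons of ``genes`` for every individual."""
    rng = np.random.default_rng(rng)
    pos_blocks, mean_blocks = [], {}
    inds, species_of = [], {}
    for sp, n in spec.individuals.items():
        for k in range(n):
            name = f"{sp}_{k}"
            inds.append(name)
            species_of[name] = sp

    positions = []
    gene_of_site = []
    for g in genes:
        for s, e in g.exons:
            positions.append(np.arange(s, e))
            gene_of_site.extend([g.gene_id] * (e - s))
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    gene_of_site = np.asarray(gene_of_site)

    data = {"CHROM": np.full(len(pos), chrom), "POS": pos}
    for name in inds:
        sp = species_of[name]
        copies = np.array([spec.copy_number.get(sp, {}).get(g, 1)
                           for g in gene_of_site], dtype=float)
        mu = spec.coverage * copies
        if spec.overdispersion is None:
            d = rng.poisson(mu)
        else:
            k = spec.overdispersion
            lam = np.where(mu > 0, rng.gamma(k, np.maximum(mu, 1e-300) / k), 0.0)
            d = rng.poisson(lam)
        d = np.where(copies == 0, 0, d)
        data[name] = d.astype(np.int64)
    df = pd.DataFrame(data)
    return DepthTable(depth=df, species_of=species_of,
                      true_copies={sp: dict(g) for sp, g in spec.copy_number.items()})
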
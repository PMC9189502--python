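"""Gene copy number from normalized read depth.

Copy number is read off relative depth: only exonic sites with at least
one read in *every* individual are considered (masking regions of poor
cross-species mappability), per-gene per-individual median depths are
normalized by that individual's median across all genes on the
chromosome — which assumes most genes are single-copy — and rounded to
the nearest integer (half away from zero). Species-level copy number is
the median over the species' individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simgenome.chromosome import GeneModel
from .simgenome.depths import DepthTable

__all__ = ["mask_sites", "gene_median_depth", "copy_number",
           "estimate_copy_numbers"]


def _exon_lookup(genes: Sequence[GeneModel]):
    """Map positions to gene ids via sorted exon intervals."""
    starts, ends, gids = [], [], []
    for g in genes:
        for s, e in g.exons:
            starts.append(s)
            ends.append(e)
            gids.append(g.gene_id)
    order = np.argsort(starts)
    return (np.asarray(starts)[order], np.asarray(ends)[order],
            np.asarray(gids, dtype=object)[order])


def assign_genes(pos: np.ndarray, genes: Sequence[GeneModel]) -> np.ndarray:
    """Gene id per position (object array; None outside every exon).

    Exons are assumed non-overlapping across genes, as in the simulator
    and in single-isoform annotations.
    """
    starts, ends, gids = _exon_lookup(genes)
    out = np.full(len(pos), None, dtype=object)
    if len(starts) == 0:
        return out
    k = np.searchsorted(starts, pos, side="right") - 1
    ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
    out[ok] = gids[k[ok]]
    return out


def mask_sites(table: DepthTable, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Keep exonic sites where every individual has depth ≥ 1.

    Returns the depth frame restricted to usable sites, with a ``gene``
    column attached.
    """
    inds = table.individuals
    if not set(table.species_of) >= set(inds):
        missing = sorted(set(inds) - set(table.species_of))
        raise ValueError(f"individuals without a species assignment: {missing}")
    df = table.depth
    gene = assign_genes(df["POS"].to_numpy(), genes)
    exonic = np.array([g is not None for g in gene])
    covered = (df[inds].to_numpy() >= 1).all(axis=1)
    out = df.loc[exonic & covered].copy()
    out["gene"] = gene[exonic & covered]
    return out


def gene_median_depth(masked: pd.DataFrame, min_sites: int = 100,
                      ) -> pd.DataFrame:
    """Per-gene per-individual median depth over surviving exonic sites.

    Genes with fewer than ``min_sites`` usable sites are excluded. Returns
    a frame indexed by gene id with one column per individual plus
    ``n_sites``.
    """
    inds = [c for c in masked.columns if c not in ("CHROM", "POS", "gene")]
    grouped = masked.groupby("gene", sort=True)
    med = grouped[inds].median()
    med["n_sites"] = grouped.size()
    return med.loc[med["n_sites"] >= min_sites]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def copy_number(medians: pd.DataFrame, species_of: dict[str, str],
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per individual and round to integer copies.

    Each individual's gene medians are divided by that individual's
    median across all genes on the chromosome (its single-copy depth),
    then rounded half-away-from-zero. Returns (per-individual integer
    copies, per-species median copies); individuals whose normalizer is
    zero come back as NaN.
    """
    inds = [c for c in medians.columns if c != "n_sites"]
    if len(medians) < 3:
        raise ValueError("need at least 3 genes on the chromosome for a "
                         "stable normalizer")
    norm = medians[inds].median(axis=0)
    normalized = medians[inds] / norm.replace(0, np.nan)
    per_ind = normalized.apply(lambda col: _round_half_away(col.to_numpy()))
    per_ind = pd.DataFrame(per_ind, index=medians.index, columns=inds)

    species = sorted(set(species_of[i] for i in inds))
    per_sp = pd.DataFrame(index=medians.index, columns=species, dtype=float)
    for sp in species:
        cols = [i for i in inds if species_of[i] == sp]
        per_sp[sp] = _round_half_away(per_ind[cols].median(axis=1).to_numpy())
    return per_ind, per_sp


def estimate_copy_numbers(table: DepthTable, genes: Sequence[GeneModel],
                          min_sites: int = 100,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: site masking → gene medians → normalized copies."""
    masked = mask_sites(table, genes)
    medians = gene_median_depth(masked, min_sites=min_sites)
    return copy_number(medians, table.species_of)
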
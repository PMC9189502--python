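"""Fourfold-degenerate-site divergence and calibrated molecular dating.

Third codon positions where all four bases encode the same amino acid are
putatively neutral; net divergence d_a = d_XY − (π_A + π_B)/2 restricted
to those sites approximates the substitution distance accumulated since
two lineages split. Dividing by the same quantity for a calibration pair
of known age converts it to absolute time under a strict clock:

    age = calibration_age × d_a(focal) / d_a(calibration)

Confidence intervals on d_a come from a block bootstrap over genes
(sites within a gene are linked; genes are treated as exchangeable),
and are propagated through the calibration by the same scaling with the
calibration point held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._seq import BASES, MISSING
from .winstats import dxy, pi

__all__ = ["fourfold_mask", "fourfold_mask_consensus", "DaEstimate",
           "da_at_sites", "CalibratedAge", "calibrate_age"]

_FWD = standard_dna_table.forward_table


def _aa(codon: str) -> str | None:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return _FWD.get(codon)


# degeneracy of every dinucleotide prefix, precomputed from the code table
_FOURFOLD_PREFIX = frozenset(
    p for p in (a + b for a in BASES for b in BASES)
    if len({_aa(p + n) for n in BASES}) == 1 and _aa(p + "A") is not None
)


def fourfold_mask(cds: str) -> np.ndarray:
    """Boolean mask over CDS positions: True at fourfold third positions.

    A third position is fourfold iff the four codons sharing its first
    two bases all translate to the same amino acid. Any non-ACGT
    character in the first two codon positions demotes the site.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    cds = cds.upper()
    mask = np.zeros(len(cds), dtype=bool)
    for i in range(0, len(cds), 3):
        mask[i + 2] = cds[i:i + 2] in _FOURFOLD_PREFIX
    return mask


def fourfold_mask_consensus(cds_seqs: list[str]) -> np.ndarray:
    """Fourfold mask agreed across several aligned CDS sequences.

    A site counts only if it is fourfold in every sequence *and* the
    codon context (positions 1–2) is identical across sequences — codon
    context disagreement demotes the site.
    """
    if not cds_seqs:
        raise ValueError("no sequences")
    masks = [fourfold_mask(s) for s in cds_seqs]
    agree = np.logical_and.reduce(masks)
    ref = cds_seqs[0].upper()
    for s in cds_seqs[1:]:
        s = s.upper()
        for i in range(2, len(ref), 3):
            if agree[i] and (s[i - 2] != ref[i - 2] or s[i - 1] != ref[i - 1]):
                agree[i] = False
    return agree


def fourfold_site_table(ref_cds: dict[str, str], genes,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome positions of fourfold sites, with their gene ids.

    ``ref_cds`` maps gene id → spliced reference CDS (translation order);
    ``genes`` are the matching :class:`GeneModel` records. Degeneracy is
    classified from the reference codon context.
    """
    pos_list, gid_list = [], []
    for g in genes:
        cds = ref_cds[g.gene_id]
        mask = fourfold_mask(cds)
        cds_pos = g.cds_positions()
        pos_list.append(cds_pos[mask])
        gid_list.extend([g.gene_id] * int(mask.sum()))
    pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    return pos[order], np.asarray(gid_list, dtype=object)[order]


@dataclass(frozen=True)
class DaEstimate:
    da: float
    dxy: float
    pi_a: float
    pi_b: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_sites: int = 0


def _da(alleles_a: np.ndarray, alleles_b: np.ndarray) -> tuple[float, float, float, float]:
    d = dxy(alleles_a, alleles_b)
    pa = pi(alleles_a) if alleles_a.shape[1] > 1 else 0.0
    pb = pi(alleles_b) if alleles_b.shape[1] > 1 else 0.0
    pa = 0.0 if np.isnan(pa) else pa
    pb = 0.0 if np.isnan(pb) else pb
    return d - (pa + pb) / 2, d, pa, pb


def da_at_sites(alleles_a: np.ndarray, alleles_b: np.ndarray,
                gene_ids: np.ndarray | None = None,
                n_bootstrap: int = 1_000, ci: float = 95.0,
                rng: np.random.Generator | int | None = None) -> DaEstimate:
    """Net divergence over a set of (fourfold) sites with a bootstrap CI.

    ``alleles_a``/``alleles_b``: (S, k) allele-code arrays (one column for
    a haploid sample, two per diploid), already restricted to the sites of
    interest. ``gene_ids`` labels each site's gene for the block
    bootstrap; without it no CI is computed. Groups with a single allele
    column have π fixed at 0.
    """
    if alleles_a.shape[0] != alleles_b.shape[0]:
        raise ValueError("groups cover different numbers of sites")
    da, d, pa, pb = _da(alleles_a, alleles_b)
    lo = hi = None
    if gene_ids is not None and n_bootstrap > 0:
        rng = np.random.default_rng(rng)
        genes = np.unique(gene_ids)
        site_idx = {g: np.flatnonzero(gene_ids == g) for g in genes}
        reps = np.empty(n_bootstrap)
        for r in range(n_bootstrap):
            pick = rng.choice(len(genes), size=len(genes), replace=True)
            idx = np.concatenate([site_idx[genes[g]] for g in pick])
            reps[r], *_ = _da(alleles_a[idx], alleles_b[idx])
        tail = (100.0 - ci) / 2
        lo, hi = np.percentile(reps, [tail, 100.0 - tail])
    return DaEstimate(da=float(da), dxy=float(d), pi_a=float(pa), pi_b=float(pb),
                      ci_low=lo if lo is None else float(lo),
                      ci_high=hi if hi is None else float(hi),
                      n_sites=int(alleles_a.shape[0]))


@dataclass(frozen=True)
class CalibratedAge:
    focal_da: float
    calib_da: float
    calib_age_ma: float
    age_ma: float
    ci_low_ma: float | None = None
    ci_high_ma: float | None = None


def calibrate_age(focal_da: float, calib_da: float, calib_age_ma: float,
                  focal_ci: tuple[float, float] | None = None) -> CalibratedAge:
    """Convert focal net divergence to absolute time via a calibration pair.

    age = calib_age × focal_da / calib_da; a focal CI is scaled the same
    way with the calibration treated as an exact constant.
    """
    if calib_da <= 0:
        raise ValueError("calibration d_a must be positive")
    scale = calib_age_ma / calib_da
    lo = hi = None
    if focal_ci is not None:
        lo, hi = sorted(focal_ci)
        lo, hi = lo * scale, hi * scale
    return CalibratedAge(focal_da=focal_da, calib_da=calib_da,
                         calib_age_ma=calib_age_ma, age_ma=focal_da * scale,
                         ci_low_ma=lo, ci_high_ma=hi)
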
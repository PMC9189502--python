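"""Windowed diversity, divergence and ancestry painting.

Statistics follow the standard population-genetic definitions on allele
pairs: π is the mean per-site pairwise difference among the 2n alleles of
a panel (within-individual pairs included), d_XY the mean per-site
difference across all between-group allele pairs, and d_a = d_XY − π (or
minus the mean of the two panels' π for a panel-pair track) — the net
divergence accumulated since the split. Windows contain a fixed number of
*genotyped* sites rather than a fixed physical span, so painting
resolution tracks data density.

Painting assigns each window of a haploid target assembly to the
reference panel with the lowest d_a, provided the runner-up is at least a
margin behind (default 0.01) and every panel clears a minimum genotyped-
site count in at least one of its individuals (default 10,000 of 25,000).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import MISSING
from .genotypes import GenotypeMatrix

__all__ = [
    "PanelSpec", "Window", "filter_genotypes", "window_partition",
    "pi", "dxy", "window_stats", "paint_windows",
    "pairwise_divergence_track", "write_painting_bed9",
]

UNASSIGNED = "UNASSIGNED"
MASKED = "MASKED"


@dataclass(frozen=True)
class PanelSpec:
    """Reference panels: name → member individual ids (disjoint)."""

    members: dict[str, tuple[str, ...]]

    def __post_init__(self):
        seen: set[str] = set()
        for name, ids in self.members.items():
            if not ids:
                raise ValueError(f"panel {name!r} is empty")
            dup = seen.intersection(ids)
            if dup:
                raise ValueError(f"individuals {sorted(dup)} in multiple panels")
            seen.update(ids)

    @property
    def names(self) -> list[str]:
        return list(self.members)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelSpec":
        members: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                ind, panel = line.split()[:2]
                members.setdefault(panel, []).append(ind)
        return cls({k: tuple(v) for k, v in members.items()})


@dataclass(frozen=True)
class Window:
    chrom: str
    start_idx: int      # site-index bounds into the matrix, half-open
    end_idx: int
    start_pos: int      # genomic position bounds (first/last site)
    end_pos: int
    partial: bool = False


def filter_genotypes(mat: GenotypeMatrix, min_dp: int = 0,
                     min_gq: int = 0) -> GenotypeMatrix:
    """Set calls failing DP/GQ thresholds (inclusive) to missing.

    Sites are never removed here. A matrix without DP/GQ annotations is
    returned unchanged when both thresholds are 0, and rejected otherwise.
    """
    if min_dp <= 0 and min_gq <= 0:
        return mat
    fail = np.zeros((mat.n_sites, len(mat.samples)), dtype=bool)
    if min_dp > 0:
        if mat.dp is None:
            raise ValueError("min_dp set but matrix carries no DP annotations")
        fail |= mat.dp < min_dp
    if min_gq > 0:
        if mat.gq is None:
            raise ValueError("min_gq set but matrix carries no GQ annotations")
        fail |= mat.gq < min_gq
    gt = mat.gt.copy()
    gt[fail] = MISSING
    return GenotypeMatrix(chrom=mat.chrom, pos=mat.pos, samples=list(mat.samples),
                          gt=gt, target_name=mat.target_name, target=mat.target,
                          dp=mat.dp, gq=mat.gq)


def window_partition(mat: GenotypeMatrix, sites_per_window: int = 25_000,
                     anchor: str = "target") -> list[Window]:
    """Cut each chromosome into consecutive fixed-site-count windows.

    ``anchor`` chooses which sites count toward the quota: "target" (sites
    genotyped in the haploid target — the assembly being painted) or "any"
    (sites genotyped in at least one sample). The trailing window of a
    chromosome is flagged partial when it falls short of the quota.
    """
    if sites_per_window <= 0:
        raise ValueError("sites_per_window must be positive")
    if anchor == "target":
        if mat.target is None:
            raise ValueError("anchor='target' requires a target column")
        counts = (mat.target != MISSING)
    elif anchor == "any":
        counts = (mat.gt[:, :, 0] != MISSING).any(axis=1)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    windows: list[Window] = []
    for chrom in pd.unique(mat.chrom):
        idx = np.flatnonzero(mat.chrom == chrom)
        anchored = idx[counts[idx]]
        lo = idx[0]
        if len(anchored) == 0:
            # no anchoring site at all: one undefined partial window
            windows.append(Window(
                chrom=str(chrom), start_idx=int(lo), end_idx=int(idx[-1]) + 1,
                start_pos=int(mat.pos[lo]), end_pos=int(mat.pos[idx[-1]]) + 1,
                partial=True))
            continue
        for w0 in range(0, len(anchored), sites_per_window):
            chunk = anchored[w0:w0 + sites_per_window]
            partial = len(chunk) < sites_per_window
            # the window spans from after the previous window up to its
            # last anchored site (or chromosome end for the trailing one)
            hi = chunk[-1] + 1 if not partial else idx[-1] + 1
            windows.append(Window(
                chrom=str(chrom), start_idx=int(lo), end_idx=int(hi),
                start_pos=int(mat.pos[lo]), end_pos=int(mat.pos[hi - 1]) + 1,
                partial=partial))
            lo = hi
    return windows


def _allele_counts(alleles: np.ndarray) -> np.ndarray:
    """(S, 4) counts of each base among non-missing alleles."""
    S = alleles.shape[0]
    counts = np.zeros((S, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (alleles == b).sum(axis=1)
    return counts


def pi(alleles: np.ndarray) -> float:
    """Mean pairwise difference per site among a group's alleles.

    ``alleles``: (S, k) codes with -1 missing. Sites with fewer than two
    non-missing alleles are skipped; returns NaN if no site qualifies.
    """
    c = _allele_counts(alleles)
    n = c.sum(axis=1)
    ok = n >= 2
    if not ok.any():
        return float("nan")
    c, n = c[ok], n[ok]
    same = (c * (c - 1)).sum(axis=1) / (n * (n - 1))
    return float(np.mean(1.0 - same))


def dxy(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """Mean between-group pairwise difference per site.

    Sites lacking a non-missing allele in either group are skipped.
    """
    ca, cb = _allele_counts(alleles_a), _allele_counts(alleles_b)
    na, nb = ca.sum(axis=1), cb.sum(axis=1)
    ok = (na >= 1) & (nb >= 1)
    if not ok.any():
        return float("nan")
    same = (ca[ok] * cb[ok]).sum(axis=1) / (na[ok] * nb[ok])
    return float(np.mean(1.0 - same))


def _panel_site_counts(gt_slice: np.ndarray) -> int:
    """Max over the panel's individuals of their genotyped-site counts."""
    per_ind = (gt_slice[:, :, 0] != MISSING).sum(axis=0)
    return int(per_ind.max())


def window_stats(mat: GenotypeMatrix, panels: PanelSpec,
                 sites_per_window: int = 25_000,
                 min_sites_per_panel: int = 10_000,
                 margin: float = 0.01,
                 anchor: str = "target") -> pd.DataFrame:
    """Per-window π, target d_XY/d_a per panel, and painting assignment.

    Returns one row per window with columns chrom, start, end, sites,
    partial, sites_<panel>, pi_<panel>, dxy_<panel>, da_<panel>,
    assignment. Partial trailing windows get stats but are excluded from
    painting (assignment UNASSIGNED).
    """
    if mat.target is None:
        raise ValueError("painting requires a haploid target column")
    windows = window_partition(mat, sites_per_window, anchor=anchor)
    rows = []
    idx_of = {p: mat.sample_index(panels.members[p]) for p in panels.names}
    for w in windows:
        sl = slice(w.start_idx, w.end_idx)
        tgt = mat.target[sl][:, None]
        row: dict = {"chrom": w.chrom, "start": w.start_pos, "end": w.end_pos,
                     "sites": int((mat.target[sl] != MISSING).sum()),
                     "partial": w.partial}
        da_by_panel: dict[str, float] = {}
        sites_by_panel: dict[str, int] = {}
        for p in panels.names:
            g = mat.gt[sl][:, idx_of[p], :]
            alle = g.reshape(g.shape[0], -1)
            p_pi = pi(alle)
            p_dxy = dxy(tgt, alle)
            row[f"sites_{p}"] = sites_by_panel[p] = _panel_site_counts(g)
            row[f"pi_{p}"] = p_pi
            row[f"dxy_{p}"] = p_dxy
            row[f"da_{p}"] = p_dxy - p_pi
            da_by_panel[p] = p_dxy - p_pi
        if w.partial:
            row["assignment"] = UNASSIGNED
        else:
            row["assignment"] = paint_windows(
                da_by_panel, sites_by_panel,
                margin=margin, min_sites_per_panel=min_sites_per_panel)
        rows.append(row)
    return pd.DataFrame(rows)


def paint_windows(da_by_panel: dict[str, float],
                  sites_by_panel: dict[str, int] | None = None, *,
                  margin: float = 0.01,
                  min_sites_per_panel: int = 10_000) -> str:
    """Assign one window: lowest-d_a panel wins by at least ``margin``.

    A window where any panel fails the minimum genotyped-site requirement
    is MASKED; a window whose best two panels are separated by less than
    the margin is UNASSIGNED.
    """
    if sites_by_panel is not None:
        if any(sites_by_panel[p] < min_sites_per_panel for p in da_by_panel):
            return MASKED
    valid = {p: d for p, d in da_by_panel.items() if np.isfinite(d)}
    if len(valid) < 2:
        return UNASSIGNED
    ranked = sorted(valid.items(), key=lambda kv: kv[1])
    if ranked[1][1] - ranked[0][1] >= margin:
        return ranked[0][0]
    return UNASSIGNED


def pairwise_divergence_track(mat: GenotypeMatrix, panels: PanelSpec,
                              panel_a: str, panel_b: str,
                              sites_per_window: int = 25_000,
                              anchor: str = "any") -> pd.DataFrame:
    """Windowed d_XY and d_a between two panels.

    d_a subtracts the average of the two panels' π from d_XY. Windows
    with no usable site report NaN, not zero.
    """
    ia = mat.sample_index(panels.members[panel_a])
    ib = mat.sample_index(panels.members[panel_b])
    rows = []
    for w in window_partition(mat, sites_per_window, anchor=anchor):
        sl = slice(w.start_idx, w.end_idx)
        a = mat.gt[sl][:, ia, :].reshape(w.end_idx - w.start_idx, -1)
        b = mat.gt[sl][:, ib, :].reshape(w.end_idx - w.start_idx, -1)
        pa, pb, d = pi(a), pi(b), dxy(a, b)
        rows.append({
            "chrom": w.chrom, "start": w.start_pos, "end": w.end_pos,
            "partial": w.partial,
            f"pi_{panel_a}": pa, f"pi_{panel_b}": pb,
            "dxy": d, "da": d - (pa + pb) / 2,
        })
    return pd.DataFrame(rows)


_PALETTE = ["230,171,2", "27,158,119", "117,112,179", "217,95,2",
            "231,41,138", "102,166,30"]


def write_painting_bed9(stats: pd.DataFrame, panels: PanelSpec,
                        path: str | Path) -> None:
    """Painting track: one colour per panel; grey for UNASSIGNED/MASKED."""
    colour = {p: _PALETTE[i % len(_PALETTE)] for i, p in enumerate(panels.names)}
    colour[UNASSIGNED] = "189,189,189"
    colour[MASKED] = "99,99,99"
    with open(path, "w") as fh:
        for _, r in stats.iterrows():
            fh.write("\t".join(map(str, [
                r["chrom"], r["start"], r["end"], r["assignment"], 0, ".",
                r["start"], r["end"], colour[r["assignment"]]])) + "\n")
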
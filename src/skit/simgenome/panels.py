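"""Site-wise simulation of diploid reference panels at specified π and d_XY.

Panels are generated under a biallelic star model that is exactly solvable
for the two quantities the downstream statistics estimate. Each site has
an ancestral base and one alternative base; panel p's consensus carries
the alternative with probability m_p, and every individual allele in the
panel is further flipped with probability a_p. Writing u = 1 − 2a and
v = 1 − 2m, the expected pairwise difference between two alleles is
0.5·(1 − Π of the u/v factors separating them), so

    π_p      = 0.5·(1 − u_p²)
    d_XY(pq) = 0.5·(1 − v_p·v_q·u_p·u_q)

and the model parameters are recovered from the spec'd π and d_XY in
closed form (a least-squares star decomposition when more than two panels
constrain the v's). This is a site-independent stand-in, not a coalescent:
there is no linkage, no shared polymorphism beyond the star structure,
and no mutation-rate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ..genotypes import GenotypeMatrix
from .._seq import MISSING


@dataclass
class PanelSimSpec:
    """Study conditions for a simulated panel set.

    ``panels`` maps panel name → number of diploid individuals; ``pi``
    maps panel → within-panel per-site diversity; ``dxy`` maps unordered
    panel pairs (frozenset) → between-panel per-site divergence;
    ``target_panel`` names the panel the haploid target is drawn from.
    """

    panels: dict[str, int]
    pi: dict[str, float]
    dxy: dict[frozenset, float]
    target_panel: str | None = None
    missing_prob: float = 0.0

    def __post_init__(self):
        names = list(self.panels)
        if len(names) < 1:
            raise ValueError("need at least one panel")
        for p in names:
            if not 0 <= self.pi.get(p, 0.0) < 0.5:
                raise ValueError(f"pi[{p}] must be in [0, 0.5)")
        for p, q in combinations(names, 2):
            key = frozenset((p, q))
            if key not in self.dxy:
                raise ValueError(f"missing dxy for pair {p}-{q}")
            d = self.dxy[key]
            if not (self.pi[p] < d and self.pi[q] < d):
                raise ValueError(
                    f"dxy[{p}-{q}]={d} must exceed both within-panel pi values")
            if d >= 0.5:
                raise ValueError("dxy must be < 0.5 under the biallelic model")
        if not 0 <= self.missing_prob <= 1:
            raise ValueError("missing_prob must be in [0, 1]")
        if self.target_panel is not None and self.target_panel not in self.panels:
            raise ValueError(f"unknown target panel {self.target_panel!r}")


def _solve_star(spec: PanelSimSpec) -> tuple[dict[str, float], dict[str, float]]:
    """Per-panel flip probabilities (a_p) and consensus-mutation
    probabilities (m_p) reproducing the spec'd π and d_XY."""
    names = list(spec.panels)
    u = {p: float(np.sqrt(1 - 2 * spec.pi.get(p, 0.0))) for p in names}
    a = {p: (1 - u[p]) / 2 for p in names}
    if len(names) == 1:
        return a, {names[0]: 0.0}
    pairs = list(combinations(names, 2))
    # v_p·v_q = (1 − 2·dxy) / (u_p·u_q)  →  linear system in log v
    A = np.zeros((len(pairs), len(names)))
    b = np.zeros(len(pairs))
    for r, (p, q) in enumerate(pairs):
        target = (1 - 2 * spec.dxy[frozenset((p, q))]) / (u[p] * u[q])
        if target <= 0:
            raise ValueError("dxy too large for the biallelic model")
        A[r, names.index(p)] = 1
        A[r, names.index(q)] = 1
        b[r] = np.log(target)
    logv, *_ = np.linalg.lstsq(A, b, rcond=None)
    v = np.exp(logv)
    if (v > 1 + 1e-9).any():
        raise ValueError("dxy matrix is not representable as a star "
                         "(implied negative mutation probability)")
    m = {p: float((1 - min(v[i], 1.0)) / 2) for i, p in enumerate(names)}
    return a, m


def simulate_panel_genotypes(spec: PanelSimSpec, n_sites: int,
                             rng: np.random.Generator | int | None = None,
                             chrom: str = "chr1") -> GenotypeMatrix:
    """Draw a genotype matrix whose realized π/d_XY converge to the spec.

    Sites are independent; positions are consecutive from 0. Missing
    genotypes knock out both alleles of an individual call. The haploid
    target, when requested, is one extra allele drawn from its panel of
    origin (never missing).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(rng)
    a, m = _solve_star(spec)
    names = list(spec.panels)

    anc = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    alt = (anc + rng.integers(1, 4, size=n_sites)) % 4

    sample_names: list[str] = []
    cols: list[np.ndarray] = []
    consensus_state: dict[str, np.ndarray] = {}
    for p in names:
        consensus_state[p] = rng.random(n_sites) < m[p]
        for k in range(spec.panels[p]):
            sample_names.append(f"{p}_{k}")
            flips = rng.random((n_sites, 2)) < a[p]
            state = consensus_state[p][:, None] ^ flips
            cols.append(np.where(state, alt[:, None], anc[:, None]).astype(np.int8))
    gt = np.stack(cols, axis=1)

    if spec.missing_prob > 0:
        miss = rng.random((n_sites, len(sample_names))) < spec.missing_prob
        gt[miss] = MISSING

    target = None
    if spec.target_panel is not None:
        p = spec.target_panel
        state = consensus_state[p] ^ (rng.random(n_sites) < a[p])
        target = np.where(state, alt, anc).astype(np.int8)

    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom), pos=np.arange(n_sites, dtype=np.int64),
        samples=sample_names, gt=gt,
        target_name="target" if target is not None else None, target=target,
    )
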
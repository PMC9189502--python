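"""Haplotypes with per-base ancestral provenance, and structural edits.

Every simulated haplotype carries a coordinate map recording, for each of
its bases, which ancestral position it descends from and in which
orientation, plus whether a point substitution has hit it since the
ancestor. Structural events (duplication, inversion, deletion,
translocation) rewrite sequence and map together, so ground-truth
alignments can be emitted exactly. Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import decode, encode, revcomp

NOVEL = -1

EVENT_KINDS = ("duplication", "inversion", "deletion", "translocation",
               "point_mutation_burst")


@dataclass(frozen=True)
class StructuralEvent:
    """One structural edit applied to a haplotype.

    ``start``/``end`` delimit the source tract (half-open, current
    coordinates). ``insertion_point`` is required for duplications and
    translocations and is given in pre-event coordinates; it must not fall
    strictly inside the source tract. ``orientation`` is the strand of the
    inserted copy. ``count`` is the number of substitutions for a
    ``point_mutation_burst`` (whose tract is [start, end)).
    """

    kind: str
    start: int = 0
    end: int = 0
    insertion_point: int | None = None
    orientation: str = "+"
    count: int | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


@dataclass
class CoordinateMap:
    """Per-base provenance of a derived haplotype.

    anc[i]      ancestral position of derived base i, or NOVEL (-1)
    orient[i]   +1 if base i is in ancestral orientation, -1 if inverted
    mutated[i]  True once a point substitution has hit base i
    """

    anc: np.ndarray
    orient: np.ndarray
    mutated: np.ndarray

    @classmethod
    def identity(cls, length: int) -> "CoordinateMap":
        return cls(
            anc=np.arange(length, dtype=np.int64),
            orient=np.ones(length, dtype=np.int8),
            mutated=np.zeros(length, dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.anc)

    def copy(self) -> "CoordinateMap":
        return CoordinateMap(self.anc.copy(), self.orient.copy(), self.mutated.copy())


@dataclass
class Haplotype:
    """A simulated chromosome copy: coded sequence plus coordinate map."""

    name: str
    codes: np.ndarray
    cmap: CoordinateMap
    events: list[StructuralEvent] = field(default_factory=list)

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "Haplotype":
        codes = encode(sequence)
        return cls(name=name, codes=codes, cmap=CoordinateMap.identity(len(codes)))

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def copy(self, name: str | None = None) -> "Haplotype":
        return Haplotype(name if name is not None else self.name,
                         self.codes.copy(), self.cmap.copy(), list(self.events))


def _check_interval(hap: Haplotype, start: int, end: int) -> None:
    if not (0 <= start < end <= len(hap)):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds for haplotype "
            f"{hap.name!r} of length {len(hap)}"
        )


def _insert(hap: Haplotype, at: int, codes: np.ndarray, anc: np.ndarray,
            orient: np.ndarray, mutated: np.ndarray) -> Haplotype:
    m = hap.cmap
    return Haplotype(
        hap.name,
        np.concatenate([hap.codes[:at], codes, hap.codes[at:]]),
        CoordinateMap(
            np.concatenate([m.anc[:at], anc, m.anc[at:]]),
            np.concatenate([m.orient[:at], orient, m.orient[at:]]),
            np.concatenate([m.mutated[:at], mutated, m.mutated[at:]]),
        ),
        list(hap.events),
    )


def apply_event(hap: Haplotype, event: StructuralEvent,
                rng: np.random.Generator | None = None) -> Haplotype:
    """Apply one structural event, returning a new haplotype.

    The input is not modified. Point-mutation bursts require ``rng``.
    """
    kind = event.kind
    if kind == "point_mutation_burst":
        start = event.start
        end = event.end if event.end else len(hap)
        _check_interval(hap, start, end)
        if event.count is None or event.count < 0:
            raise ValueError("point_mutation_burst requires a non-negative count")
        if event.count > end - start:
            raise ValueError("more substitutions than sites in the tract")
        if rng is None:
            raise ValueError("point_mutation_burst requires an rng")
        out = hap.copy()
        pos = start + rng.choice(end - start, size=event.count, replace=False)
        # substitute to a uniformly chosen different base
        shift = rng.integers(1, 4, size=event.count).astype(np.uint8)
        out.codes[pos] = (out.codes[pos] + shift) % 4
        out.cmap.mutated[pos] = True
        out.events.append(event)
        return out

    start, end = event.start, event.end
    _check_interval(hap, start, end)
    m = hap.cmap

    if kind == "inversion":
        out = hap.copy()
        out.codes[start:end] = revcomp(hap.codes[start:end])
        out.cmap.anc[start:end] = m.anc[start:end][::-1]
        out.cmap.orient[start:end] = -m.orient[start:end][::-1]
        out.cmap.mutated[start:end] = m.mutated[start:end][::-1]
        out.events.append(event)
        return out

    if kind == "deletion":
        keep = np.ones(len(hap), dtype=bool)
        keep[start:end] = False
        out = Haplotype(hap.name, hap.codes[keep],
                        CoordinateMap(m.anc[keep], m.orient[keep], m.mutated[keep]),
                        list(hap.events))
        out.events.append(event)
        return out

    if event.insertion_point is None:
        raise ValueError(f"{kind} requires an insertion_point")
    p = event.insertion_point
    if not (0 <= p <= len(hap)):
        raise ValueError(f"insertion_point {p} out of bounds (length {len(hap)})")
    if start < p < end:
        raise ValueError(
            f"insertion_point {p} falls inside the source tract [{start}, {end})"
        )

    tract = hap.codes[start:end]
    t_anc = m.anc[start:end]
    t_ori = m.orient[start:end]
    t_mut = m.mutated[start:end]
    if event.orientation == "-":
        tract = revcomp(tract)
        t_anc = t_anc[::-1]
        t_ori = (-t_ori[::-1]).astype(np.int8)
        t_mut = t_mut[::-1]

    if kind == "duplication":
        out = _insert(hap, p, tract, t_anc, t_ori, t_mut)
        out.events.append(event)
        return out

    if kind == "translocation":
        keep = np.ones(len(hap), dtype=bool)
        keep[start:end] = False
        trimmed = Haplotype(hap.name, hap.codes[keep],
                            CoordinateMap(m.anc[keep], m.orient[keep], m.mutated[keep]),
                            list(hap.events))
        p_adj = p if p <= start else p - (end - start)
        out = _insert(trimmed, p_adj, tract, t_anc, t_ori, t_mut)
        out.events.append(event)
        return out

    raise AssertionError(f"unhandled event kind {kind}")  # pragma: no cover
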
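"""Replay of rearrangement histories along a labelled tree.

Each branch carries an ordered list of structural events and a per-base
substitution probability. Tips inherit every event on their root-to-tip
path, so sister tips share exactly the events of their shared branches —
the duplication-then-differential-loss scenario is expressed as a
duplication on a stem branch followed by different deletions on the two
descendant branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype import Haplotype, StructuralEvent, apply_event
from .chromosome import AncestralChromosome


@dataclass
class SimNode:
    """A node of the event-annotated tree.

    ``events`` happen on the branch leading INTO this node, in list order;
    ``subs_rate`` is the per-base substitution probability on that branch
    (the number of substitutions is binomial in the current haplotype
    length). A node with no children is a tip and names a haplotype.
    """

    name: str
    events: list[StructuralEvent] = field(default_factory=list)
    subs_rate: float = 0.0
    children: list["SimNode"] = field(default_factory=list)

    def tips(self) -> list["SimNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


def _evolve_branch(hap: Haplotype, node: SimNode,
                   rng: np.random.Generator) -> Haplotype:
    for ev in node.events:
        hap = apply_event(hap, ev, rng)
    if node.subs_rate > 0:
        n_subs = int(rng.binomial(len(hap), node.subs_rate))
        if n_subs:
            burst = StructuralEvent("point_mutation_burst", 0, len(hap),
                                    count=n_subs)
            hap = apply_event(hap, burst, rng)
    return hap


def simulate_allele_histories(ancestor: AncestralChromosome, tree: SimNode,
                              rng: np.random.Generator | int | None = None,
                              ) -> dict[str, Haplotype]:
    """Evolve the ancestor down the tree; returns one haplotype per tip.

    Every event is validated against the haplotype state at its branch
    (an out-of-bounds event raises). The per-haplotype event log is kept
    on each returned :class:`Haplotype` as ground truth.
    """
    rng = np.random.default_rng(rng)
    root_hap = Haplotype.from_sequence(ancestor.name, ancestor.sequence)
    tips: dict[str, Haplotype] = {}

    def walk(node: SimNode, hap: Haplotype) -> None:
        hap = _evolve_branch(hap, node, rng)
        if not node.children:
            if node.name in tips:
                raise ValueError(f"duplicate tip name {node.name!r}")
            tips[node.name] = hap.copy(name=node.name)
        for child in node.children:
            walk(child, hap)

    walk(tree, root_hap)
    return tips


def random_history(length: int, rng: np.random.Generator, *,
                   n_events: int | None = None, max_events: int = 5,
                   min_tract: int = 50_000, max_tract: int = 200_000,
                   kinds: tuple[str, ...] = ("inversion", "duplication",
                                             "deletion", "translocation"),
                   ) -> tuple[list[StructuralEvent], list[dict]]:
    """Draw a valid random event history with disjoint ancestral footprints.

    Source tracts and insertion anchors are planned on the ancestral
    coordinate system so no event disturbs another's footprint; each
    event's coordinates are then translated to the haplotype state at its
    turn. Returns (events in application order, truth records carrying
    each event's kind and ancestral interval). Histories built this way
    keep every event individually recoverable — overlapping events whose
    signals cancel or fragment are never drawn.
    """
    if n_events is None:
        n_events = int(rng.integers(1, max_events + 1))
    needs_anchor = {"duplication", "translocation"}
    for _ in range(200):   # rejection-sample a disjoint plan
        picks = [str(k) for k in rng.choice(kinds, size=n_events)]
        intervals: list[tuple[int, int]] = []
        ok = True
        for kind in picks:
            size = int(rng.integers(min_tract, max_tract + 1))
            for _try in range(50):
                s = int(rng.integers(0, length - size))
                if all(e0 >= s + size or s >= e1 for e0, e1 in intervals):
                    intervals.append((s, s + size))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        # anchors are drawn only once every source tract is fixed, so an
        # inserted copy can never land inside a later event's footprint
        anchors: list[int | None] = []
        for kind in picks:
            if kind not in needs_anchor:
                anchors.append(None)
                continue
            for _try in range(50):
                p = int(rng.integers(0, length))
                if all(not (e0 - 1 <= p < e1 + 1) for e0, e1 in intervals) \
                        and p not in anchors:
                    anchors.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not place disjoint events; chromosome too small")

    events: list[StructuralEvent] = []
    truth: list[dict] = []
    hap = Haplotype.from_sequence("plan", "A" * length)
    for kind, (a0, a1), anchor in zip(picks, intervals, anchors):
        cur = hap.cmap.anc
        cs = int(np.flatnonzero(cur == a0)[0])
        ce = int(np.flatnonzero(cur == a1 - 1)[0]) + 1
        kwargs: dict = {"kind": kind, "start": cs, "end": ce}
        if anchor is not None:
            kwargs["insertion_point"] = int(np.flatnonzero(cur == anchor)[0])
            kwargs["orientation"] = str(rng.choice(["+", "-"]))
        ev = StructuralEvent(**kwargs)
        hap = apply_event(hap, ev)
        events.append(ev)
        truth.append({"kind": kind, "anc_start": a0, "anc_end": a1,
                      "orientation": kwargs.get("orientation", "+")})
    return events, truth
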
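"""Pairwise alignment records and PAF / show-coords I/O.

PAF is the 12-column minimap2 format plus typed tags; only the ``dv:f:``
per-alignment divergence tag is interpreted. Records are ref(target)-
centric internally; both interval pairs are 0-based half-open on the
forward strand of their sequence, per the PAF convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["AlignmentRecord", "read_paf", "write_paf", "read_showcoords"]


@dataclass(frozen=True)
class AlignmentRecord:
    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    ref_len: int = 0
    query_len: int = 0
    n_matches: int = 0
    aligned_length: int = 0
    mapq: int = 60
    dv: float | None = None

    def __post_init__(self):
        if self.ref_start >= self.ref_end or self.query_start >= self.query_end:
            raise ValueError("alignment intervals must be non-empty (start < end)")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.aligned_length == 0:
            object.__setattr__(self, "aligned_length",
                               max(self.ref_end - self.ref_start,
                                   self.query_end - self.query_start))


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read minimap2-style PAF; the query is column 1, the target is the ref."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            dv = None
            for tag in f[12:]:
                if tag.startswith("dv:f:"):
                    dv = float(tag[5:])
                elif tag.startswith("de:f:") and dv is None:
                    dv = float(tag[5:])
            records.append(AlignmentRecord(
                query_name=f[0], query_len=int(f[1]),
                query_start=int(f[2]), query_end=int(f[3]),
                strand=f[4],
                ref_name=f[5], ref_len=int(f[6]),
                ref_start=int(f[7]), ref_end=int(f[8]),
                n_matches=int(f[9]), aligned_length=int(f[10]),
                mapq=int(f[11]), dv=dv,
            ))
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.query_name, r.query_len, r.query_start, r.query_end,
                    r.strand, r.ref_name, r.ref_len, r.ref_start, r.ref_end,
                    r.n_matches, r.aligned_length, r.mapq]
            line = "\t".join(str(c) for c in cols)
            if r.dv is not None:
                line += f"\tdv:f:{r.dv:.6f}"
            fh.write(line + "\n")


def read_showcoords(path: str | Path) -> list[AlignmentRecord]:
    """Read MUMmer ``show-coords -T`` tab output (with or without headers).

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY ... TAG_REF TAG_QRY. Coordinates
    are 1-based inclusive; a query interval with start > end means the
    minus strand.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            try:
                s1, e1, s2, e2 = (int(f[i]) for i in range(4))
            except ValueError:
                continue  # header lines
            strand = "+" if s2 <= e2 else "-"
            if strand == "-":
                s2, e2 = e2, s2
            idy = float(f[6])
            records.append(AlignmentRecord(
                ref_name=f[-2], ref_start=s1 - 1, ref_end=e1,
                query_name=f[-1], query_start=s2 - 1, query_end=e2,
                strand=strand, n_matches=0,
                aligned_length=max(e1 - s1 + 1, e2 - s2 + 1),
                dv=max(0.0, 1.0 - idy / 100.0),
            ))
    return records
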
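"""Nucleotide encodings shared across the package.

Bases are stored internally as uint8 codes 0..3 = A,C,G,T; -1 (or 255)
never appears in assembled haplotypes — missing data exists only in
genotype matrices, where it is coded -1 in int8 arrays.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
MISSING = -1

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_CHAR = np.frombuffer(BASES.encode(), dtype=np.uint8)

# IUPAC ambiguity codes as sorted base-code tuples.
IUPAC_TO_BASES = {
    "A": (A,), "C": (C,), "G": (G,), "T": (T,),
    "R": (A, G), "Y": (C, T), "S": (C, G), "W": (A, T),
    "K": (G, T), "M": (A, C),
    "B": (C, G, T), "D": (A, G, T), "H": (A, C, T), "V": (A, C, G),
    "N": (A, C, G, T),
}
BASES_TO_IUPAC = {v: k for k, v in IUPAC_TO_BASES.items()}

_IUPAC_COMPLEMENT = {}
for _k, _v in IUPAC_TO_BASES.items():
    _IUPAC_COMPLEMENT[_k] = BASES_TO_IUPAC[tuple(sorted(3 - b for b in _v))]
_IUPAC_COMPLEMENT["N"] = "N"
_IUPAC_COMPLEMENT["-"] = "-"


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to uint8 codes; raises on non-ACGT characters."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr.astype(np.uint8)


def decode(codes: np.ndarray) -> str:
    return _CHAR[codes].tobytes().decode()


def complement(codes: np.ndarray) -> np.ndarray:
    """Complement of coded bases (A<->T, C<->G is 3 - code)."""
    return (3 - codes.astype(np.int16)).astype(codes.dtype)


def revcomp(codes: np.ndarray) -> np.ndarray:
    return complement(codes)[::-1]


def revcomp_str(seq: str) -> str:
    """Reverse complement of a string, IUPAC-aware."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


def iupac_from_pair(a: int, b: int) -> str:
    """IUPAC character for an unordered diploid genotype of base codes."""
    if a == b:
        return BASES[a]
    return BASES_TO_IUPAC[tuple(sorted((a, b)))]
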
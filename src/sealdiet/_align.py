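"""Shared sequence-comparison primitives.

Identity here is fraction of matching columns over the longer sequence
length, computed from a global edit-distance alignment (free end gaps are
irrelevant for the near-full-length amplicons this package handles, and a
Hamming fast path covers the equal-length case that dominates in practice).
"""

from __future__ import annotations

import edlib

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

# edlib equalities: treat bases with overlapping IUPAC sets as equal
_EQUALITIES = [
    (a, b)
    for a in _IUPAC
    for b in _IUPAC
    if a < b and _IUPAC[a] & _IUPAC[b]
]


def bases_match(a: str, b: str) -> bool:
    """True if the IUPAC sets of two bases intersect."""
    sa = _IUPAC.get(a.upper())
    sb = _IUPAC.get(b.upper())
    if sa is None or sb is None:
        return a.upper() == b.upper()
    return bool(sa & sb)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (IUPAC-aware)."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(not bases_match(x, y) for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    """Plain Levenshtein edit distance (no ambiguity codes)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def edit_distance_iupac(a: str, b: str) -> int:
    """Global edit distance where intersecting IUPAC codes count as equal."""
    return edlib.align(
        a.upper(), b.upper(), task="distance", additionalEqualities=_EQUALITIES
    )["editDistance"]


def identity(a: str, b: str) -> float:
    """Global-alignment identity in [0, 1].

    1 - edit_distance / max(len); equals the p-distance complement for
    equal-length sequences and penalises length differences as gaps.
    """
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        return 1.0 - hamming(a.upper(), b.upper()) / len(a)
    d = edit_distance_iupac(a, b)
    return 1.0 - d / max(len(a), len(b))


def p_distance(a: str, b: str) -> float:
    """Pairwise distance in [0, 1]; 0.0 iff the sequences are identical
    (up to IUPAC-compatible bases)."""
    return 1.0 - identity(a, b)
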
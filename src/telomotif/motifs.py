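"""Rotation/strand equivalence classes of tandem repeat motifs.

A telomeric repeat can be detected in any rotational phase and on either
strand: a TTAGGC telomere may surface as AGGCTT, GCTTAG, or (on the
complementary strand) GCCTAA.  For ranking and plotting, all of these must
count as one unit.  This module canonicalizes a motif into its
rotation/strand class and provides a rotation- and strand-invariant Hamming
distance between classes (useful for spotting sequencing-error neighbours
of a true telomeric motif, which typically sit at distance 1-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "MotifClass",
    "reverse_complement",
    "canonical_class",
    "class_distance",
    "rotations",
    "min_rotation",
    "primitive_root",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
_VALID_MOTIF = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N pairs with N."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(s: str) -> list[str]:
    """All cyclic rotations of ``s`` (with duplicates removed, order kept)."""
    seen, out = set(), []
    for i in range(len(s)):
        r = s[i:] + s[:i]
        if r not in seen:
            seen.add(r)
            out.append(r)
    return out


def min_rotation(s: str) -> str:
    """Lexicographically smallest cyclic rotation of ``s``."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def primitive_root(s: str) -> str:
    """Shortest ``u`` such that ``s == u * k`` for an integer ``k >= 1``."""
    n = len(s)
    for d in range(1, n):
        if n % d == 0 and s == s[:d] * (n // d):
            return s[:d]
    return s


@dataclass(frozen=True)
class MotifClass:
    """Rotation/strand equivalence class of a primitive repeat motif.

    canonical_key
        Lexicographically smallest string among all rotations of the motif
        and all rotations of its reverse complement; the class identity.
    display_motif
        The orientation used for plotting: the G-rich strand (more G than
        C), rotated to its lexicographically smallest phase.  This is the
        conventional telomere orientation pointing toward the chromosome
        end (the "blue" curve); the reverse complement is the C-rich strand.
    """

    canonical_key: str
    display_motif: str
    period: int
    is_palindromic_class: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display_motif


@lru_cache(maxsize=65536)
def canonical_class(motif: str) -> MotifClass:
    """Map a motif to its rotation/strand class.

    The motif is first reduced to its primitive root (an integer power of a
    shorter motif collapses onto that motif).  All rotations of the reduced
    motif and of its reverse complement share one canonical key.

    Display orientation rule: prefer the strand with more G than C; on a
    tie, the strand whose minimal rotation is lexicographically smaller.
    Within the chosen strand, display the lexicographically smallest
    rotation.  The rule is deterministic, so palindromic and G=C classes
    still get a unique display motif.
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    if not set(motif) <= _VALID_MOTIF:
        bad = sorted(set(motif) - _VALID_MOTIF)
        raise ValueError(f"motif contains characters outside ACGT: {bad}")
    motif = primitive_root(motif)
    rc = reverse_complement(motif)
    min_fwd = min_rotation(motif)
    min_rev = min_rotation(rc)
    key = min(min_fwd, min_rev)
    palindromic = min_fwd == min_rev

    g, c = motif.count("G"), motif.count("C")
    if g > c:
        display = min_fwd
    elif c > g:
        display = min_rev
    else:
        display = min(min_fwd, min_rev)
    return MotifClass(
        canonical_key=key,
        display_motif=display,
        period=len(motif),
        is_palindromic_class=palindromic,
    )


def class_distance(a: MotifClass, b: MotifClass) -> int:
    """Minimum Hamming distance between classes over rotations and strands.

    Defined only for classes of equal period (the distance between units of
    different length is not a Hamming distance; the caller decides how to
    handle those).
    """
    if a.period != b.period:
        raise ValueError(
            f"class_distance undefined for unequal periods "
            f"({a.period} vs {b.period})"
        )
    ref = a.canonical_key
    candidates = rotations(b.canonical_key) + rotations(
        reverse_complement(b.canonical_key)
    )
    return min(
        sum(x != y for x, y in zip(ref, cand)) for cand in candidates
    )
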
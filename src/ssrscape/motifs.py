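"""Motif-level utilities: primitivity, rotations, complement classes.

A repeat motif is *primitive* when it has no shorter exact tiling period
(``GA`` is primitive, ``GAGA`` is not).  Motif *classes* group every
rotation of a motif together with every rotation of its reverse
complement, the grouping conventionally used when SSR annotations pool
complementary and frame-shifted dimers (CA = AC = GT = TG, AT = TA, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def _check_acgt(s: str) -> None:
    if not s:
        raise ValueError("empty motif")
    if not _ALPHABET.issuperset(s):
        raise ValueError(f"motif {s!r} contains non-ACGT characters")


def revcomp(s: str) -> str:
    """Reverse complement of an ACGT string."""
    _check_acgt(s)
    return s.translate(_COMPLEMENT)[::-1]


def primitive_motif(s: str) -> str:
    """Smallest unit whose exact concatenation reproduces ``s``.

    >>> primitive_motif("GAGA")
    'GA'
    >>> primitive_motif("AAA")
    'A'
    >>> primitive_motif("GAT")
    'GAT'
    """
    _check_acgt(s)
    n = len(s)
    for d in range(1, n + 1):
        if n % d == 0 and s == s[:d] * (n // d):
            return s[:d]
    raise AssertionError("unreachable")  # d == n always tiles


def is_primitive(s: str) -> bool:
    return primitive_motif(s) == s


def rotations(s: str) -> set[str]:
    """All cyclic rotations of ``s`` (a set; duplicates collapse)."""
    return {s[i:] + s[:i] for i in range(len(s))}


@dataclass(frozen=True)
class MotifClass:
    """A rotation/reverse-complement equivalence class of motifs.

    ``label`` is the lexicographically smallest member and names the
    class; ``members`` holds every motif string belonging to it.
    """

    label: str
    members: frozenset[str]

    def __contains__(self, motif: str) -> bool:
        return motif in self.members

    @property
    def size(self) -> int:
        return len(self.members)


def motif_class_members(motif: str) -> MotifClass:
    """Class of ``motif``: rotations of it and of its reverse complement.

    The motif must be primitive; class size always divides
    ``2 * len(motif)`` (palindromic or self-complementary motifs collapse
    members).
    """
    _check_acgt(motif)
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    members = rotations(motif) | rotations(revcomp(motif))
    return MotifClass(label=min(members), members=frozenset(members))


def motif_class_label(motif: str) -> str:
    """Canonical class label for a primitive motif (cached)."""
    try:
        return _LABEL_CACHE[motif]
    except KeyError:
        label = motif_class_members(motif).label
        _LABEL_CACHE[motif] = label
        return label


_LABEL_CACHE: dict[str, str] = {}
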
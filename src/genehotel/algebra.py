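"""Klein-group arithmetic and the 4x4x4 triplet lattice.

The four RNA nucleotides ``{C, U, A, G}`` carry the Klein four-group
structure induced by the identification ``C=00, U=01, A=10, G=11`` with
bitwise addition mod 2 (so every element is its own inverse and ``C`` is
neutral).  A *triplet* is a 3-letter RNA string; under a chosen
:class:`Ordering` of the four nucleotides each triplet gets integer
coordinates in ``{0..3}^3``, turning the 64 triplets into a cubic lattice
equipped with the Manhattan metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

NUCLEOTIDES = ("C", "U", "A", "G")

#: Klein numeral of each nucleotide in the canonical order {C, U, A, G}.
_KLEIN_NUM = {"C": 0, "U": 1, "A": 2, "G": 3}
_KLEIN_SYM = {v: k for k, v in _KLEIN_NUM.items()}

#: Watson-Crick complement on the RNA alphabet.
_COMPLEMENT = {"C": "G", "G": "C", "U": "A", "A": "U"}

#: Degenerate position symbols: N = any, Y = pyrimidine, R = purine.
_PATTERN_CLASSES = {
    "N": ("C", "U", "A", "G"),
    "Y": ("C", "U"),
    "R": ("A", "G"),
    "C": ("C",),
    "U": ("U",),
    "A": ("A",),
    "G": ("G",),
}

#: Subgroup-with-a-tail: the 8-triplet subset of the rear wall CNN whose
#: Klein translates by GCC and AAU are the two shared-anticodon sets of the
#: human tRNA code.
SGWT = frozenset({"CCC", "CUC", "CCU", "CUU", "CCA", "CUA", "CAA", "CUG"})

ALL_TRIPLETS = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)
)


def _check_nucleotide(x: str) -> str:
    if x not in _KLEIN_NUM:
        raise ValueError(f"invalid RNA nucleotide {x!r}; expected one of C, U, A, G")
    return x


def _check_triplet(t: str) -> str:
    if len(t) != 3 or any(b not in _KLEIN_NUM for b in t):
        raise ValueError(f"invalid RNA triplet {t!r}; expected 3 letters over C, U, A, G")
    return t


def klein_add(a: str, b: str) -> str:
    """Klein four-group sum of two nucleotides (XOR of their binary duplets)."""
    _check_nucleotide(a)
    _check_nucleotide(b)
    return _KLEIN_SYM[_KLEIN_NUM[a] ^ _KLEIN_NUM[b]]


def klein_add_triplet(t: str, v: str) -> str:
    """Component-wise Klein sum of two triplets (a lattice translation)."""
    _check_triplet(t)
    _check_triplet(v)
    return "".join(klein_add(a, b) for a, b in zip(t, v))


def complement(x: str) -> str:
    """Watson-Crick complement: C<->G, U<->A."""
    _check_nucleotide(x)
    return _COMPLEMENT[x]


def reverse_complement(t: str) -> str:
    """Reverse complement of a triplet, read 5'->3' on both strands.

    On lattice coordinates under the canonical ordering this is the
    composition of the corner translation by GGG with the reflection that
    swaps the first and third axes.
    """
    _check_triplet(t)
    return "".join(_COMPLEMENT[b] for b in reversed(t))


@dataclass(frozen=True)
class Ordering:
    """A linear order of the four nucleotides, written as a 4-letter string.

    The ordering fixes the lattice embedding: the i-th base of a triplet
    contributes its rank (0..3) on the i-th coordinate axis.  An ordering and
    its reverse produce the same unlabeled cube, which is why only 12 of the
    24 permutations give distinct quotient graphs.
    """

    sequence: str

    def __post_init__(self) -> None:
        if sorted(self.sequence) != sorted(NUCLEOTIDES):
            raise ValueError(
                f"ordering {self.sequence!r} is not a permutation of C, U, A, G"
            )

    @property
    def rank(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.sequence)}

    def reversed(self) -> "Ordering":
        return Ordering(self.sequence[::-1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.sequence


CANONICAL_ORDERING = Ordering("CUAG")


def _as_ordering(o: "Ordering | str") -> Ordering:
    return o if isinstance(o, Ordering) else Ordering(o)


def triplet_coords(t: str, o: "Ordering | str" = CANONICAL_ORDERING) -> tuple[int, int, int]:
    """Lattice coordinates of a triplet: position i maps to axis i."""
    _check_triplet(t)
    rank = _as_ordering(o).rank
    return (rank[t[0]], rank[t[1]], rank[t[2]])


def manhattan(t1: str, t2: str, o: "Ordering | str" = CANONICAL_ORDERING) -> int:
    """Manhattan (taxi-cab) distance between two triplets on the lattice."""
    c1 = triplet_coords(t1, o)
    c2 = triplet_coords(t2, o)
    return sum(abs(a - b) for a, b in zip(c1, c2))


def is_adjacent(t1: str, t2: str, o: "Ordering | str" = CANONICAL_ORDERING) -> bool:
    """True iff the triplets differ in one position by consecutive ranks."""
    return manhattan(t1, t2, o) == 1


def named_subset(name: str) -> frozenset[str]:
    """A named subset of the 64 triplets.

    ``name`` is either the literal ``"SGwT"`` (the subgroup-with-a-tail of
    the rear wall CNN) or a 3-letter pattern over ``{N, Y, R, C, U, A, G}``
    read position-wise: N = any base, Y = pyrimidine {C, U}, R = purine
    {A, G}, a literal base matches itself.  Examples: ``"NNC"`` (first
    floor), ``"GNN"`` (front wall), ``"RNY"`` (the 16 primeval codons),
    ``"YYY"`` (the all-pyrimidine corner subcube).
    """
    if name == "SGwT":
        return SGWT
    if len(name) != 3 or any(p not in _PATTERN_CLASSES for p in name):
        raise ValueError(
            f"unknown subset name {name!r}; expected 'SGwT' or a 3-letter "
            "pattern over N, Y, R, C, U, A, G"
        )
    return frozenset(
        "".join(p)
        for p in itertools.product(*(_PATTERN_CLASSES[c] for c in name))
    )


def translate_set(s: Iterable[str], v: str) -> frozenset[str]:
    """Image of a triplet set under the Klein translation by ``v``.

    Translations by corner triplets (all components in {C, G}) are
    isometric; a general translation such as by AAU need not preserve
    Manhattan distances.
    """
    _check_triplet(v)
    return frozenset(klein_add_triplet(t, v) for t in s)
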
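"""Finite isometry groups of the triplet lattice.

Every isometry of the 4x4x4 triplet cube decomposes uniquely as a corner
translation composed with an axis permutation, ``T_v . M``, where ``v`` is a
triplet with components in {C, G} and ``M`` is one of the six 3x3
permutation matrices.  The full Euclidean group of the cube has 6 x 8 = 48
elements: the semidirect product of the order-6 axis-permutation group
(isomorphic to the dihedral group D3) with the order-8 elementary abelian
group of corner translations.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable

from genehotel.algebra import ALL_TRIPLETS, klein_add_triplet

#: Axis permutations as source-index tuples: applying ``p`` to a triplet t
#: yields u with u[i] = t[p[i]].  A is the 3-cycle e1->e2->e3->e1, B swaps
#: the second and third axes; together they generate all six permutations.
PERM_IDENTITY = (0, 1, 2)
PERM_A = (2, 0, 1)
PERM_B = (0, 2, 1)
#: P13 swaps the first and third axes (the reversal of a triplet).
PERM_P13 = (2, 1, 0)

_NULL_TRANS = "CCC"


@dataclass(frozen=True)
class Isometry:
    """An isometry in normal form: translation ``trans`` after axis
    permutation ``perm`` (source-index convention)."""

    trans: str = _NULL_TRANS
    perm: tuple[int, int, int] = PERM_IDENTITY

    def __post_init__(self) -> None:
        if len(self.trans) != 3 or any(b not in "CG" for b in self.trans):
            raise ValueError(
                f"isometric translations have components in {{C, G}}; got {self.trans!r}"
            )
        if sorted(self.perm) != [0, 1, 2]:
            raise ValueError(f"invalid axis permutation {self.perm!r}")

    def apply(self, t: str) -> str:
        """Image of triplet ``t``: permute axes, then Klein-translate."""
        permuted = t[self.perm[0]] + t[self.perm[1]] + t[self.perm[2]]
        return klein_add_triplet(permuted, self.trans)

    def __call__(self, t: str) -> str:
        return self.apply(t)

    @property
    def name(self) -> str:
        perm_names = {
            PERM_IDENTITY: "I",
            PERM_A: "A",
            (1, 2, 0): "A2",
            PERM_B: "B",
            (1, 0, 2): "AB",
            PERM_P13: "A2B",
        }
        p = perm_names[self.perm]
        if self.trans == _NULL_TRANS:
            return p
        t = f"T_{self.trans}"
        return t if p == "I" else f"{t}*{p}"


IDENTITY = Isometry()
A = Isometry(perm=PERM_A)
B = Isometry(perm=PERM_B)
P13 = Isometry(perm=PERM_P13)
T_GCC = Isometry(trans="GCC")
T_CGC = Isometry(trans="CGC")
T_CCG = Isometry(trans="CCG")
#: Translation by GGG; composed with P13 it is the reverse-complement map.
T_GGG = Isometry(trans="GGG")


def compose(g1: Isometry, g2: Isometry) -> Isometry:
    """Composition ``g1 . g2`` (apply g2 first), in normal form.

    ``(T_v1 M1)(T_v2 M2) = T_(v1 + M1 v2) (M1 M2)`` because conjugating a
    translation by an axis permutation permutes its components.
    """
    permuted_v2 = (
        g2.trans[g1.perm[0]] + g2.trans[g1.perm[1]] + g2.trans[g1.perm[2]]
    )
    trans = klein_add_triplet(g1.trans, permuted_v2)
    perm = tuple(g2.perm[g1.perm[i]] for i in range(3))
    return Isometry(trans=trans, perm=perm)  # type: ignore[arg-type]


def inverse(g: Isometry) -> Isometry:
    """Group inverse: ``(T_v M)^-1 = T_(M^-1 v) M^-1`` (translations are
    involutions)."""
    inv_perm = [0, 0, 0]
    for i, j in enumerate(g.perm):
        inv_perm[j] = i
    inv_perm = tuple(inv_perm)
    trans = g.trans[inv_perm[0]] + g.trans[inv_perm[1]] + g.trans[inv_perm[2]]
    return Isometry(trans=trans, perm=inv_perm)  # type: ignore[arg-type]


def element_order(g: Isometry) -> int:
    power, n = g, 1
    while power != IDENTITY:
        power = compose(g, power)
        n += 1
    return n


@dataclass(frozen=True)
class IsometryGroup:
    """A finite group of lattice isometries, closed under composition."""

    elements: frozenset[Isometry]
    generators: frozenset[Isometry] = field(default_factory=frozenset)

    @property
    def order(self) -> int:
        return len(self.elements)

    def __contains__(self, g: Isometry) -> bool:
        return g in self.elements

    def __iter__(self):
        return iter(sorted(self.elements, key=lambda g: (g.trans, g.perm)))

    def is_abelian(self) -> bool:
        els = list(self.elements)
        return all(
            compose(g, h) == compose(h, g)
            for i, g in enumerate(els)
            for h in els[i + 1 :]
        )

    def element_orders(self) -> dict[int, int]:
        """Census: group-element order -> multiplicity."""
        census: dict[int, int] = {}
        for g in self.elements:
            n = element_order(g)
            census[n] = census.get(n, 0) + 1
        return census

    def is_subgroup_of(self, other: "IsometryGroup") -> bool:
        return self.elements <= other.elements

    def to_json(self) -> str:
        """Elements in normal form as a JSON list."""
        return json.dumps(
            [{"trans": g.trans, "perm": list(g.perm), "name": g.name} for g in self],
            indent=1,
        )

    def write_cayley_csv(self, path) -> None:
        els = list(self)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["*"] + [g.name for g in els])
            for g in els:
                writer.writerow([g.name] + [compose(g, h).name for h in els])


def closure(generators: Iterable[Isometry]) -> IsometryGroup:
    """Smallest group containing the generators (fixed-point iteration)."""
    gens = frozenset(generators)
    elements = {IDENTITY, *gens}
    frontier = set(elements)
    while frontier:
        new = set()
        for g in frontier:
            for h in gens:
                for prod in (compose(g, h), compose(h, g)):
                    if prod not in elements:
                        new.add(prod)
        elements |= new
        frontier = new
    return IsometryGroup(elements=frozenset(elements), generators=gens)


def euclidean_group() -> IsometryGroup:
    """The full order-48 Euclidean group of the triplet cube, generated by
    the axis permutations A, B and the corner translations T_GCC, T_CGC,
    T_CCG."""
    return closure({A, B, T_GCC, T_CGC, T_CCG})


def translation_group() -> IsometryGroup:
    """The order-8 elementary abelian group of corner translations."""
    return closure({T_GCC, T_CGC, T_CCG})


def stabilizer(group: IsometryGroup, s: Iterable[str]) -> IsometryGroup:
    """Setwise stabilizer of a triplet set, found by brute force."""
    target = frozenset(s)
    kept = frozenset(
        g for g in group.elements if frozenset(g(t) for t in target) == target
    )
    return IsometryGroup(elements=kept)


def orbit(group: IsometryGroup, t: str) -> frozenset[str]:
    return frozenset(g(t) for g in group.elements)


def preserves_manhattan(g: Isometry, ordering="CUAG") -> bool:
    """Exhaustive check that ``g`` preserves all pairwise Manhattan
    distances under the given ordering."""
    from genehotel.algebra import manhattan

    return all(
        manhattan(g(t1), g(t2), ordering) == manhattan(t1, t2, ordering)
        for i, t1 in enumerate(ALL_TRIPLETS)
        for t2 in ALL_TRIPLETS[i + 1 :]
    )


def classify_small_group(group: IsometryGroup) -> str:
    """Isomorphism-class label for groups of order at most 8.

    The label is decided from the order, commutativity and the census of
    element orders, which suffices to separate all groups of order <= 8
    (in particular the dihedral group of order 8 has five involutions
    while the quaternion group has exactly one).
    """
    n = group.order
    if n == 1:
        return "trivial"
    if n > 8:
        return f"unclassified(order={n})"
    census = group.element_orders()
    abelian = group.is_abelian()
    exponent = max(census)
    if abelian:
        if exponent == n:
            return f"cyclic({n})"
        if exponent == 2:
            return f"elementary_abelian({n})"
        if n == 8 and exponent == 4:
            return "abelian(4x2)"
        return f"unclassified(order={n})"
    if n == 6:
        return "dihedral(6)"
    if n == 8:
        if census.get(2, 0) == 1:
            return "quaternion(8)"
        if census.get(2, 0) == 5:
            return "dihedral(8)"
    return f"unclassified(order={n})"
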
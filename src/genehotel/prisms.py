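"""Triangular-prism motif census, coloring and connectivity analysis.

The triangular prism is the 6-vertex 3-regular graph made of two disjoint
triangles ("caps") joined by a perfect matching — the Cayley graph of
Z3 x Z2.  In induced mode a 6-vertex subset counts only if its induced
subgraph is exactly a prism; in non-induced mode it counts if the induced
subgraph contains a spanning prism.  Records are deduplicated by vertex
set: two different matchings on the same six labels count once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from genehotel.codes import PropertyTable


@dataclass(frozen=True)
class PrismRecord:
    vertices: tuple[str, ...]
    caps: tuple[tuple[str, ...], tuple[str, ...]]
    ordering: str | None = None
    code: str | None = None
    induced: bool = True

    def to_dict(self) -> dict:
        return {
            "vertices": list(self.vertices),
            "caps": [list(c) for c in self.caps],
            "ordering": self.ordering,
            "code": self.code,
            "induced": self.induced,
        }


def _spanning_prism_caps(g: nx.Graph, six: tuple[str, ...]):
    """Caps of a spanning prism on the 6 vertices, or None.

    Searches unordered pairs of vertex-disjoint triangles connected by a
    perfect matching among the present edges.
    """
    triangles = [
        tri
        for tri in itertools.combinations(six, 3)
        if g.has_edge(tri[0], tri[1])
        and g.has_edge(tri[0], tri[2])
        and g.has_edge(tri[1], tri[2])
    ]
    for t1, t2 in itertools.combinations(triangles, 2):
        if set(t1) & set(t2):
            continue
        for perm in itertools.permutations(t2):
            if all(g.has_edge(a, b) for a, b in zip(t1, perm)):
                return (tuple(sorted(t1)), tuple(sorted(t2)))
    return None


def find_prisms(g: nx.Graph, induced: bool = True) -> list[PrismRecord]:
    """All 6-vertex subsets carrying a triangular prism, sorted by label.

    ``induced=True`` requires the induced subgraph to be exactly the prism
    graph (nine edges, 3-regular, with a triangle — which rules out the
    only other cubic graph on six vertices, the triangle-free K33).
    """
    records = []
    nodes = sorted(g.nodes)
    ordering = g.graph.get("ordering")
    code = g.graph.get("code")
    for six in itertools.combinations(nodes, 6):
        sub = g.subgraph(six)
        if induced:
            if sub.number_of_edges() != 9 or any(d != 3 for _, d in sub.degree):
                continue
        elif sub.number_of_edges() < 9:
            continue
        caps = _spanning_prism_caps(sub, six)
        if caps is None:
            continue
        records.append(
            PrismRecord(
                vertices=six, caps=caps, ordering=ordering, code=code,
                induced=induced,
            )
        )
    return records


@dataclass(frozen=True)
class PrismCensus:
    """Per-ordering prism records for one code's 12 quotient graphs."""

    code: str
    induced: bool
    records: dict[str, tuple[PrismRecord, ...]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {o: len(rs) for o, rs in self.records.items()}

    @property
    def orderings_with_prism(self) -> tuple[str, ...]:
        return tuple(sorted(o for o, rs in self.records.items() if rs))

    def composition_classes(self) -> frozenset[frozenset[str]]:
        """Distinct 6-label vertex sets across all records."""
        return frozenset(
            frozenset(r.vertices) for rs in self.records.values() for r in rs
        )

    def amino_acids_in_prisms(self) -> frozenset[str]:
        return frozenset().union(frozenset(), *self.composition_classes())

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "induced": self.induced,
            "orderings_with_prism": list(self.orderings_with_prism),
            "counts": self.counts,
            "records": {
                o: [r.to_dict() for r in rs] for o, rs in self.records.items()
            },
        }


def prism_census(
    code: str, induced: bool = True, orderings: "Iterable | None" = None
) -> PrismCensus:
    """Run the prism search over a code's quotient graphs (default: the 12
    canonical orderings)."""
    from genehotel.phenograph import code_graphs

    graphs = code_graphs(code, orderings)
    records = {
        g.graph["ordering"]: tuple(find_prisms(g, induced=induced))
        for g in graphs
    }
    name = code if isinstance(code, str) else code.name
    return PrismCensus(code=name, induced=induced, records=records)


def color_graph(g: nx.Graph, p: PropertyTable) -> dict[str, str]:
    """Assign each vertex its property bin class ('q1'..'q4', or 'mixed'
    for amino acids flagged as spanning two classes).  Stop vertices have
    no property value and raise."""
    missing = [v for v in g.nodes if v not in p.values and v not in p.mixed]
    if missing:
        raise ValueError(
            f"no {p.name} value for vertices: {', '.join(sorted(missing))}"
        )
    return {v: p.class_of(v) for v in sorted(g.nodes)}


def cut_vertices(g: nx.Graph) -> frozenset[str]:
    """Articulation points: vertices whose removal disconnects their
    component."""
    return frozenset(nx.articulation_points(g))
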
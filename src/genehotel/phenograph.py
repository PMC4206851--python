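"""Triplet graphs and amino-acid quotient ("phenotypic") graphs.

A triplet graph puts an edge between two triplets whenever their Manhattan
distance under a given nucleotide ordering is one.  Quotienting by the
synonymy relation (codons encoding the same amino acid) collapses the 64
vertices to the amino-acid labels; two labels are adjacent iff some pair of
their triplets is adjacent.  Because an ordering and its reverse give the
same cube up to reflection, the 24 orderings yield at most 12 distinct
quotient graphs per code.
"""

from __future__ import annotations

import csv
import itertools
from typing import Iterable, Mapping

import networkx as nx

from genehotel.algebra import (
    ALL_TRIPLETS,
    NUCLEOTIDES,
    Ordering,
    _as_ordering,
    is_adjacent,
)
from genehotel.codes import (
    AnticodonTable,
    CodeTable,
    human_anticodons,
    sgc,
    standard_anticodons,
)


def enumerate_orderings() -> list[Ordering]:
    """The 12 canonical orderings: one representative per {ordering,
    reverse} pair, the lexicographically smaller member, sorted."""
    reps = sorted(
        "".join(p)
        for p in itertools.permutations(NUCLEOTIDES)
        if "".join(p) < "".join(reversed(p))
    )
    return [Ordering(s) for s in reps]


def triplet_graph(s: Iterable[str], o: "Ordering | str") -> nx.Graph:
    """Graph on a triplet set with edges at Manhattan distance one."""
    o = _as_ordering(o)
    vertices = sorted(s)
    g = nx.Graph(ordering=o.sequence)
    g.add_nodes_from(vertices)
    for t1, t2 in itertools.combinations(vertices, 2):
        if is_adjacent(t1, t2, o):
            g.add_edge(t1, t2)
    return g


def full_triplet_graph(o: "Ordering | str") -> nx.Graph:
    """The complete 64-triplet lattice graph (144 edges)."""
    return triplet_graph(ALL_TRIPLETS, o)


def quotient_graph(
    g: nx.Graph, labeling: "CodeTable | Mapping[str, str]", code: str = "custom"
) -> nx.Graph:
    """Quotient of a triplet graph by a labeling.

    Vertices are the labels occurring on the triplet set; two distinct
    labels are joined iff some triplet of one is adjacent to some triplet
    of the other (self-pairs are discarded).
    """
    mapping = labeling.mapping if isinstance(labeling, CodeTable) else labeling
    unlabeled = [t for t in g.nodes if t not in mapping]
    if unlabeled:
        raise ValueError(f"unlabeled vertices: {', '.join(sorted(unlabeled))}")
    q = nx.Graph(ordering=g.graph.get("ordering"), code=code)
    q.add_nodes_from(sorted({mapping[t] for t in g.nodes}))
    for t1, t2 in g.edges:
        a, b = mapping[t1], mapping[t2]
        if a != b:
            q.add_edge(*sorted((a, b)))
    return q


def _trna_graph(table: AnticodonTable, o: "Ordering | str") -> nx.Graph:
    """Quotient graph of a tRNA code: triplet graph induced on the used
    anticodons, labeled by the amino acid each anticodon serves (no Stop
    vertex; the initiator species is merged with Met)."""
    labels = table.anticodon_labels(sgc())
    g = triplet_graph(sorted(labels), o)
    return quotient_graph(g, labels, code=table.name)


_BUILTIN_CODES = ("sgc", "std-trna", "human-trna")


def code_graph(
    code: "str | CodeTable | AnticodonTable", o: "Ordering | str"
) -> nx.Graph:
    """One quotient graph for a code under one ordering.

    For a codon code (the SGC or a custom :class:`CodeTable`) the quotient
    is over the full 64-triplet graph, Stop included.  For a tRNA code the
    quotient is over the used-anticodon triplets, Stop absent.
    """
    if isinstance(code, CodeTable):
        return quotient_graph(full_triplet_graph(o), code, code=code.name)
    if isinstance(code, AnticodonTable):
        return _trna_graph(code, o)
    if code == "sgc":
        return quotient_graph(full_triplet_graph(o), sgc(), code="sgc")
    if code == "std-trna":
        return _trna_graph(standard_anticodons(), o)
    if code == "human-trna":
        return _trna_graph(human_anticodons(), o)
    raise ValueError(f"unknown code {code!r}; expected one of {_BUILTIN_CODES}")


def code_graphs(
    code: "str | CodeTable | AnticodonTable",
    orderings: "Iterable[Ordering | str] | None" = None,
) -> list[nx.Graph]:
    """The quotient graphs of a code, one per ordering (default: the 12
    canonical orderings)."""
    if orderings is None:
        orderings = enumerate_orderings()
    return [code_graph(code, o) for o in orderings]


def universal_edges(graphs: Iterable[nx.Graph]) -> frozenset[frozenset[str]]:
    """Edges present in every graph; the graphs must share a vertex set."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs given")
    vertex_sets = {frozenset(g.nodes) for g in graphs}
    if len(vertex_sets) != 1:
        raise ValueError("graphs do not share a vertex set")
    common = frozenset(frozenset(e) for e in graphs[0].edges)
    for g in graphs[1:]:
        common &= frozenset(frozenset(e) for e in g.edges)
    return common


def subgraph_violations(
    sub: nx.Graph, sup: nx.Graph
) -> frozenset[frozenset[str]]:
    """Edges of ``sub`` between shared vertices that are absent from
    ``sup`` (empty iff ``sub`` is an edge-subgraph of ``sup`` on the shared
    vertex set).  Used to *measure*, not assume, the claim that a tRNA
    quotient graph is a subgraph of the codon quotient graph."""
    shared = set(sub.nodes) & set(sup.nodes)
    sup_edges = {frozenset(e) for e in sup.edges}
    return frozenset(
        frozenset(e)
        for e in sub.edges
        if set(e) <= shared and frozenset(e) not in sup_edges
    )


# ---------------------------------------------------------------------------
# Export

def write_graphml(g: nx.Graph, path, colors: "Mapping[str, str] | None" = None):
    h = g.copy()
    if colors is not None:
        nx.set_node_attributes(h, dict(colors), "polar_class")
    nx.write_graphml(h, path)


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            w.writerow([a, b])


def write_adjacency_csv(g: nx.Graph, path) -> None:
    nodes = sorted(g.nodes)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + nodes)
        for a in nodes:
            w.writerow([a] + [int(g.has_edge(a, b)) for b in nodes])
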
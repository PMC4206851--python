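"""Centrality statistics and one-way ANOVA comparison across codes.

Conventions:

* degree — raw incident-edge count;
* closeness — (n_c - 1) / sum of distances within the vertex's connected
  component of size n_c (equal to the classic (n-1)/sum(d) on connected
  graphs);
* betweenness — raw shortest-path pass-through counts, endpoints excluded,
  each unordered pair counted once;
* eigenvector — principal eigenvector of the adjacency matrix by power
  iteration (uniform start, tolerance 1e-12), nonnegative and normalized
  to unit maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("degree", "closeness", "betweenness", "eigenvector")


def eigenvector_centrality(g: nx.Graph, tol: float = 1e-12, max_iter: int = 100000) -> dict[str, float]:
    """Max-normalized principal eigenvector of the adjacency matrix."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    v = np.ones(len(nodes))
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:  # edgeless graph
            v = np.zeros(len(nodes))
            break
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    if v.max() > 0:
        v = v / v.max()
    return dict(zip(nodes, v))


def centrality(g: nx.Graph) -> pd.DataFrame:
    """Per-vertex centrality table (rows: labels, columns: measures)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=False, endpoints=False)
    eigen = eigenvector_centrality(g)
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "eigenvector": [eigen[v] for v in nodes],
        },
        index=pd.Index(nodes, name="vertex"),
    )


def mean_centrality(graphs: Iterable[nx.Graph]) -> pd.DataFrame:
    """Arithmetic mean of each centrality measure over graphs sharing a
    vertex set (e.g. the 12 quotient graphs of one code)."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs given")
    if len({frozenset(g.nodes) for g in graphs}) != 1:
        raise ValueError("graphs do not share a vertex set")
    tables = [centrality(g) for g in graphs]
    return sum(tables[1:], tables[0]) / len(tables)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    measure: str | None = None
    subset: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
            "measure": self.measure,
            "subset": list(self.subset) if self.subset else None,
        }


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA from the between/within sum of
    squares decomposition; the p-value is the upper tail of the F
    distribution."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups of at least two observations")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = sum(len(a) for a in arrays) - len(arrays)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(F=0.0, df=(df_b, df_w), p=1.0)
        return AnovaResult(F=float("inf"), df=(df_b, df_w), p=0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(F=float(f), df=(df_b, df_w), p=p)


def compare_codes(
    measure: str,
    subset: "Sequence[str] | None" = None,
    mean_tables: "dict[str, pd.DataFrame] | None" = None,
) -> AnovaResult:
    """One-way ANOVA of a centrality measure across the three codes.

    Groups are the per-amino-acid mean centralities (over the 12 quotient
    graphs) of the SGC, standard tRNA and human tRNA codes, restricted to
    ``subset`` (default: the 20 amino acids, i.e. every vertex common to
    all three codes' graphs).  Precomputed ``mean_tables`` keyed by code
    name may be supplied to avoid rebuilding the 36 graphs.
    """
    if measure not in MEASURES:
        raise ValueError(f"unsupported measure {measure!r}; one of {MEASURES}")
    if mean_tables is None:
        from genehotel.phenograph import code_graphs

        mean_tables = {
            code: mean_centrality(code_graphs(code))
            for code in ("sgc", "std-trna", "human-trna")
        }
    common = set.intersection(*(set(t.index) for t in mean_tables.values()))
    if subset is None:
        subset = sorted(common)
    missing = set(subset) - common
    if missing:
        raise ValueError(
            f"subset members missing from some code's graphs: {sorted(missing)}"
        )
    groups = [
        mean_tables[code].loc[list(subset), measure].to_numpy()
        for code in sorted(mean_tables)
    ]
    result = anova_oneway(groups)
    return AnovaResult(
        F=result.F, df=result.df, p=result.p,
        measure=measure, subset=tuple(subset),
    )
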
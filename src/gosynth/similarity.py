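"""Pairwise semantic similarity between ontology terms.

Five measures are supported, all bounded in [0, 1]:

``resnik_norm``
    IC of the most informative common ancestor (MICA), normalized by the
    namespace-wide maximum IC.
``lin``
    2 * IC(MICA) / (IC(t1) + IC(t2)).
``nunivers``
    IC(MICA) / max(IC(t1), IC(t2)).
``aic``
    Aggregate information content: each term carries a logistic knowledge
    weight SW(t) = 1 / (1 + exp(-1/IC(t))) (SW = 1 at the root, the IC -> 0+
    limit); similarity is twice the summed SW over common ancestors (terms
    included) divided by the two terms' total semantic values.
``distance``
    1 - d / (2 * max_depth) where d is the shortest hierarchical-edge path
    joining the terms through a common ancestor. The exact published form of
    this measure is not fully specified; this implementation is provisional
    and kept behind the common interface.

Degenerate conventions: identical terms score 1 (even at the root, except
``resnik_norm`` whose diagonal is IC(t)/max_ic); distinct terms whose only
common ancestor carries zero IC score 0 under the MICA-based measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ontology import OntologyGraph, TermStats

MEASURES = ("resnik_norm", "lin", "aic", "nunivers", "distance")


@dataclass
class SimilarityMatrix:
    terms: list[str]
    values: np.ndarray
    measure: str

    def index(self, t: str) -> int:
        return self.terms.index(t)


def _anc_or_self(graph: OntologyGraph, t: str) -> frozenset[str]:
    return frozenset(graph.ancestors(t)) | {t}


def mica(
    graph: OntologyGraph, stats: TermStats, t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor of two terms (terms included).

    Ties broken by lexicographically smallest identifier.
    """
    if graph.namespace[graph.resolve(t1)] != graph.namespace[graph.resolve(t2)]:
        raise ValueError(f"{t1} and {t2} are in different namespaces")
    common = _anc_or_self(graph, t1) & _anc_or_self(graph, t2)
    best = min(common, key=lambda c: (-stats.ic[c], c))
    return best, stats.ic[best]


def _sw(ic: float) -> float:
    # logistic knowledge weight; root (IC 0) takes the IC -> 0+ limit, 1
    return 1.0 if ic == 0.0 else 1.0 / (1.0 + math.exp(-1.0 / ic))


def similarity(
    measure: str, graph: OntologyGraph, stats: TermStats, t1: str, t2: str
) -> float:
    """Similarity of two same-namespace terms under the named measure."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    t1, t2 = graph.resolve(t1), graph.resolve(t2)

    if measure == "aic":
        a1, a2 = _anc_or_self(graph, t1), _anc_or_self(graph, t2)
        sv1 = sum(_sw(stats.ic[a]) for a in a1)
        sv2 = sum(_sw(stats.ic[a]) for a in a2)
        return 2.0 * sum(_sw(stats.ic[c]) for c in a1 & a2) / (sv1 + sv2)

    if measure == "distance":
        if t1 == t2:
            return 1.0
        d1, d2 = _updistances(graph, t1), _updistances(graph, t2)
        d = min(d1[c] + d2[c] for c in d1.keys() & d2.keys())
        return max(0.0, 1.0 - d / (2.0 * max(stats.max_depth, 1)))

    ic1, ic2 = stats.ic[t1], stats.ic[t2]
    _, ic_mica = mica(graph, stats, t1, t2)
    if measure == "resnik_norm":
        return ic_mica / stats.max_ic if stats.max_ic > 0 else 1.0
    if t1 == t2:
        return 1.0
    if measure == "lin":
        return 2.0 * ic_mica / (ic1 + ic2) if ic1 + ic2 > 0 else 0.0
    # nunivers
    denom = max(ic1, ic2)
    return ic_mica / denom if denom > 0 else 0.0


def _updistances(graph: OntologyGraph, t: str) -> dict[str, int]:
    """Shortest upward hierarchical-edge distance from ``t`` to each ancestor."""
    dist = {t: 0}
    frontier = [t]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for p in graph.parents(u):
                if p not in dist:
                    dist[p] = dist[u] + 1
                    nxt.append(p)
        frontier = nxt
    return dist


def similarity_matrix(
    measure: str, graph: OntologyGraph, stats: TermStats, terms: list[str]
) -> SimilarityMatrix:
    """Symmetric pairwise similarity matrix over an ordered term list."""
    n = len(terms)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = similarity(measure, graph, stats, terms[i], terms[i])
        for j in range(i + 1, n):
            s = similarity(measure, graph, stats, terms[i], terms[j])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(terms=list(terms), values=values, measure=measure)
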
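"""Ontology graph and descendant-based information content.

The ontology is a rooted DAG of terms (one root per namespace) linked by
hierarchical relations (``is_a``, ``part_of``) and regulatory relations
(``regulates`` and its positive/negative variants). Regulatory edges never
contribute to ancestry; they are consumed only by the regulation-replacement
annotation filter.

Term specificity is measured structurally, not from corpus frequencies: the
probability of a term is the product, over all of its hierarchical ancestors
``a``, of ``p(a) / |Desc(a)|``, with ``p(root) = 1``. Information content is
``IC(t) = -ln p(t)`` (nats). Evaluated entirely in log space so deep, wide
ontologies cannot underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

#: Relations that define ancestry (the GO "true path" hierarchy).
HIERARCHICAL = frozenset({"is_a", "part_of"})
#: Regulatory relations, kept separate from the hierarchy.
REGULATORY = frozenset({"regulates", "positively_regulates", "negatively_regulates"})

_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

#: GAF aspect letter for each namespace code.
ASPECT_OF_NAMESPACE = {"BP": "P", "MF": "F", "CC": "C"}
NAMESPACE_OF_ASPECT = {v: k for k, v in ASPECT_OF_NAMESPACE.items()}


class OboParseError(ValueError):
    """Raised when the OBO file cannot be parsed."""


class OntologyStructureError(ValueError):
    """Raised when the loaded graph violates DAG / rooting constraints."""


class UnknownTermError(KeyError):
    """Raised when a term identifier cannot be resolved."""


@dataclass
class OntologyGraph:
    """A typed term DAG with per-namespace roots and alias resolution."""

    terms: set[str]
    name: dict[str, str]
    namespace: dict[str, str]
    edges: set[tuple[str, str, str]]  # (child, parent, relation)
    obsolete: set[str]
    alt_ids: dict[str, str]
    roots: dict[str, str]  # namespace code -> root term

    _parents: dict[str, list[tuple[str, str]]] = field(init=False, repr=False)
    _children: dict[str, list[tuple[str, str]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._parents = {t: [] for t in self.terms}
        self._children = {t: [] for t in self.terms}
        for child, parent, rel in sorted(self.edges):
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))

    def resolve(self, term: str) -> str:
        """Resolve an identifier through the alt_id map to its canonical term."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def parents(self, t: str, relations: frozenset[str] = HIERARCHICAL) -> list[str]:
        return [p for p, rel in self._parents[t] if rel in relations]

    def children(self, t: str, relations: frozenset[str] = HIERARCHICAL) -> list[str]:
        return [c for c, rel in self._children[t] if rel in relations]

    def ancestors(self, t: str, relations: frozenset[str] = HIERARCHICAL) -> set[str]:
        """All terms reachable upward from ``t``, excluding ``t`` itself."""
        t = self.resolve(t)
        seen: set[str] = set()
        stack = list(self.parents(t, relations))
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(self.parents(u, relations))
        return seen

    def descendants(self, t: str, relations: frozenset[str] = HIERARCHICAL) -> set[str]:
        """All terms reachable downward from ``t``, excluding ``t`` itself."""
        t = self.resolve(t)
        seen: set[str] = set()
        stack = list(self.children(t, relations))
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(self.children(u, relations))
        return seen

    def regulation_target(self, t: str) -> str | None:
        """The term regulated by ``t``, or None (smallest id if several)."""
        targets = sorted(p for p, rel in self._parents[t] if rel in REGULATORY)
        return targets[0] if targets else None

    def namespace_terms(self, ns: str) -> set[str]:
        return {t for t in self.terms if self.namespace[t] == ns}

    def topological_order(self, ns: str | None = None) -> list[str]:
        """Terms ordered so every hierarchical parent precedes its children."""
        pool = self.terms if ns is None else self.namespace_terms(ns)
        ts = TopologicalSorter(
            {t: [p for p in self.parents(t) if p in pool] for t in pool}
        )
        return list(ts.static_order())


def _normalize_namespace(raw: str | None, default: str = "BP") -> str:
    if raw is None:
        return default
    try:
        return _NAMESPACE_ALIASES[raw]
    except KeyError:
        raise OboParseError(f"unknown namespace {raw!r}") from None


def parse_obo(path: str) -> OntologyGraph:
    """Load an OBO 1.2 file into an :class:`OntologyGraph`.

    Obsolete terms are recorded but carry no edges and do not appear in
    ``terms``; their incident edges are dropped. Exactly one root per
    namespace is required, and the is_a/part_of subgraph must be acyclic.
    Unknown relationship types are ignored with a warning.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboParseError(f"cannot parse OBO file {path}: {exc}") from exc

    obsolete = {
        n for n, d in g.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    }
    terms = {n for n in g.nodes if n not in obsolete}
    name: dict[str, str] = {}
    namespace: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()

    for n, d in g.nodes(data=True):
        if n in obsolete:
            continue
        name[n] = d.get("name", n)
        namespace[n] = _normalize_namespace(d.get("namespace"))
        for alias in d.get("alt_id", []):
            alt_ids[alias] = n

    known = HIERARCHICAL | REGULATORY
    for child, parent, rel in g.edges(keys=True):
        if rel not in known:
            logger.warning("ignoring unknown relationship type %r (%s -> %s)",
                           rel, child, parent)
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in terms:
            logger.warning("dropping edge to unknown term %s", parent)
            continue
        edges.add((child, parent, rel))

    hier = nx.DiGraph((c, p) for c, p, rel in edges if rel in HIERARCHICAL)
    hier.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(hier):
        cycle = nx.find_cycle(hier)
        raise OntologyStructureError(f"cycle in is_a/part_of subgraph: {cycle}")

    roots: dict[str, str] = {}
    for ns in sorted(set(namespace.values())):
        ns_terms = {t for t in terms if namespace[t] == ns}
        ns_roots = sorted(
            t for t in ns_terms
            if not any(p in ns_terms for p in hier.successors(t))
        )
        if len(ns_roots) != 1:
            raise OntologyStructureError(
                f"namespace {ns} has {len(ns_roots)} roots ({ns_roots}); expected 1"
            )
        roots[ns] = ns_roots[0]
        unreachable = ns_terms - {roots[ns]} - set(nx.ancestors(hier, roots[ns]))
        if unreachable:
            raise OntologyStructureError(
                f"terms not reaching the {ns} root: {sorted(unreachable)[:5]}"
            )

    return OntologyGraph(
        terms=terms, name=name, namespace=namespace, edges=edges,
        obsolete=obsolete, alt_ids=alt_ids, roots=roots,
    )


@dataclass
class TermStats:
    """Per-term probability, IC, depth and closure sizes for one namespace."""

    namespace: str
    root: str
    p: dict[str, float]
    ic: dict[str, float]
    depth: dict[str, int]
    n_desc: dict[str, int]
    n_anc: dict[str, int]
    max_ic: float
    max_depth: int

    @property
    def terms(self) -> set[str]:
        return set(self.ic)


def compute_ic(graph: OntologyGraph, namespace: str = "BP") -> TermStats:
    """Descendant-based information content for one namespace.

    ``log p(t)`` is accumulated as the sum over all hierarchical ancestors
    ``a`` of ``log p(a) - log |Desc(a)|`` (the log of the probability
    product), visiting terms in topological order.
    """
    ns = _NAMESPACE_ALIASES[namespace]
    if ns not in graph.roots:
        raise OntologyStructureError(f"no root for namespace {ns}")
    root = graph.roots[ns]
    order = graph.topological_order(ns)
    pool = set(order)

    anc: dict[str, frozenset[str]] = {}
    n_desc: dict[str, int] = {}
    depth: dict[str, int] = {}
    for t in order:
        ps = [p for p in graph.parents(t) if p in pool]
        anc[t] = frozenset().union(*(anc[p] | {p} for p in ps)) if ps else frozenset()
        depth[t] = max((depth[p] + 1 for p in ps), default=0)

    desc_sets: dict[str, frozenset[str]] = {}
    for t in reversed(order):
        cs = [c for c in graph.children(t) if c in pool]
        desc_sets[t] = frozenset().union(*(desc_sets[c] | {c} for c in cs)) if cs else frozenset()
        n_desc[t] = len(desc_sets[t])

    logp: dict[str, float] = {}
    for t in order:
        if t == root:
            logp[t] = 0.0
            continue
        total = 0.0
        for a in anc[t]:
            assert n_desc[a] > 0, f"ancestor {a} of {t} has zero descendants"
            total += logp[a] - math.log(n_desc[a])
        logp[t] = total

    ic = {t: -lp for t, lp in logp.items()}
    return TermStats(
        namespace=ns,
        root=root,
        p={t: math.exp(lp) for t, lp in logp.items()},
        ic=ic,
        depth=depth,
        n_desc=n_desc,
        n_anc={t: len(anc[t]) for t in order},
        max_ic=max(ic.values()),
        max_depth=max(depth.values()),
    )


#: Tolerance level -> percentile of the namespace IC distribution.
TOLERANCE_PERCENTILE = {"none": 1, "low": 10, "medium": 25, "hard": 50}


def ic_percentile_threshold(stats: TermStats, tolerance: str = "medium") -> float:
    """IC value at the tolerance's percentile (linear interpolation).

    ``medium`` (25th percentile) is the default and coincides with the first
    quartile of the IC distribution used by the incomplete-information filter.
    """
    try:
        q = TOLERANCE_PERCENTILE[tolerance]
    except KeyError:
        raise ValueError(
            f"tolerance must be one of {sorted(TOLERANCE_PERCENTILE)}, got {tolerance!r}"
        ) from None
    values = np.fromiter(stats.ic.values(), dtype=float)
    if values.size == 0:
        raise ValueError("empty IC distribution")
    return float(np.percentile(values, q, method="linear"))


def most_informative_parent_tree(
    graph: OntologyGraph, stats: TermStats, keep: Iterable[str]
) -> dict[str, str | None]:
    """Collapse the DAG to a tree by assigning each term its max-IC parent.

    Every kept term, and every term on its chosen path to the root, maps to a
    single parent (root maps to None). Ties broken by smallest identifier.
    """
    tree: dict[str, str | None] = {}
    stack = [graph.resolve(t) for t in keep]
    while stack:
        t = stack.pop()
        if t in tree:
            continue
        if t == stats.root:
            tree[t] = None
            continue
        parents = [p for p in graph.parents(t) if p in stats.ic]
        best = min(parents, key=lambda p: (-stats.ic[p], p))
        tree[t] = best
        stack.append(best)
    return tree
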
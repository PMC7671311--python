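"""Choosing and pruning representative terms for each term cluster.

A representative term stands for a whole cluster of semantically similar
terms while preserving the cluster's gene coverage. Two strategies pick the
representatives:

* majority rule — a single cluster term annotating strictly more than 70% of
  the cluster's genes is taken directly;
* frontier search (minimal set of representative terms) — otherwise, the
  sub-DAG induced by the cluster's terms and their ancestors is searched top
  down from the namespace root for the antichain of maximally specific terms
  whose combined (descendant-rolled-up) gene coverage equals the cluster's
  gene set exactly; among candidates the one with the highest mean IC wins.

The pooled representatives are then pruned: terms below the IC percentile
threshold go first, then hierarchically redundant representatives (is_a
ancestors of other representatives are dropped; of a part_of-related pair
only the better-covering member survives), and finally representatives
supporting fewer genes than a gene-set-size-dependent threshold.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

from .annotations import AnnotationTable
from .ontology import OntologyGraph, TermStats

logger = logging.getLogger(__name__)


def closure_coverage(
    graph: OntologyGraph, table: AnnotationTable, term: str
) -> set[str]:
    """Genes annotated by ``term`` or any of its hierarchical descendants."""
    genes = set(table.term_to_genes.get(term, ()))
    for d in graph.descendants(term):
        genes |= table.term_to_genes.get(d, set())
    return genes


@dataclass
class TermCluster:
    terms: set[str]
    genes: set[str]

    @classmethod
    def from_table(cls, terms: set[str], table: AnnotationTable) -> "TermCluster":
        genes: set[str] = set()
        for t in terms:
            genes |= table.term_to_genes.get(t, set())
        return cls(terms=set(terms), genes=genes)


@dataclass
class RepresentativeSet:
    reps: list[str]  # sorted for determinism
    provenance: dict[str, set[int]]  # rep -> source cluster indices
    coverage: dict[str, set[str]]  # rep -> set genes (closure within gene set)
    support_threshold: int = 1

    def _subset(self, keep: set[str]) -> "RepresentativeSet":
        return RepresentativeSet(
            reps=sorted(keep),
            provenance={t: self.provenance[t] for t in keep},
            coverage={t: self.coverage[t] for t in keep},
            support_threshold=self.support_threshold,
        )


def majority_representative(
    cluster: TermCluster,
    table: AnnotationTable,
    graph: OntologyGraph,
    stats: TermStats,
) -> str | None:
    """The single cluster term covering > 70% of the cluster's genes, if any.

    Coverage is descendant-rolled-up and restricted to the cluster's genes.
    Several qualifying terms tie-break by coverage, then IC, then identifier.
    """
    if not cluster.genes:
        return None
    qualified: list[tuple[int, float, str]] = []
    for t in sorted(cluster.terms):
        cov = len(closure_coverage(graph, table, t) & cluster.genes)
        if cov > 0.7 * len(cluster.genes):
            qualified.append((cov, stats.ic[t], t))
    if not qualified:
        return None
    qualified.sort(key=lambda q: (-q[0], -q[1], q[2]))
    return qualified[0][2]


def _induced_subdag(
    graph: OntologyGraph, cluster: TermCluster, table: AnnotationTable
) -> tuple[dict[str, list[str]], dict[str, frozenset[str]]]:
    """Children adjacency and rolled-up coverage of the cluster's sub-DAG.

    Nodes are the cluster terms plus all their hierarchical ancestors; the
    coverage of a node is the union of the cluster genes of every cluster
    term at or below it.
    """
    nodes: set[str] = set(cluster.terms)
    for t in cluster.terms:
        nodes |= graph.ancestors(t)
    children = {
        v: sorted(c for c in graph.children(v) if c in nodes) for v in nodes
    }
    cov: dict[str, set[str]] = {v: set() for v in nodes}
    for t in cluster.terms:
        genes = table.term_to_genes.get(t, set()) & cluster.genes
        cov[t] |= genes
        for a in graph.ancestors(t):
            cov[a] |= genes
    return children, {v: frozenset(g) for v, g in cov.items()}


def _is_antichain(graph: OntologyGraph, terms: frozenset[str]) -> bool:
    return not any(
        b in graph.ancestors(a) for a, b in combinations(terms, 2)
    ) and not any(a in graph.ancestors(b) for a, b in combinations(terms, 2))


def msrt(
    graph: OntologyGraph,
    stats: TermStats,
    cluster: TermCluster,
    table: AnnotationTable,
    max_subsets: int = 5000,
) -> set[str]:
    """Minimal set of representative terms by bounded frontier refinement.

    Breadth-first from {namespace root}: a frontier term is replaced by any
    subset of its sub-DAG children that keeps the frontier's combined
    coverage exactly equal to the cluster's genes. Every covering antichain
    reached is a candidate; the one with the highest mean IC wins (ties:
    fewer terms, then lexicographic).
    """
    if not cluster.genes:
        return set()
    children, cov = _induced_subdag(graph, cluster, table)
    root = stats.root
    target = frozenset(cluster.genes)

    start = frozenset({root})
    seen: set[frozenset[str]] = {start}
    queue: deque[frozenset[str]] = deque([start])
    while queue and len(seen) < max_subsets:
        state = queue.popleft()
        rest_cov: dict[str, frozenset[str]] = {}
        for v in state:
            others = frozenset().union(*(cov[u] for u in state if u != v)) \
                if len(state) > 1 else frozenset()
            rest_cov[v] = others
        for v in sorted(state):
            kids = children.get(v, [])
            if not kids:
                continue
            needed = target - rest_cov[v]
            if len(kids) <= 12:
                subsets = _covering_child_subsets(kids, cov, needed)
            else:  # bound the power set on very wide nodes
                full = frozenset(kids)
                union = frozenset().union(*(cov[c] for c in kids))
                subsets = [full] if needed <= union else []
            for sub in subsets:
                new = (state - {v}) | sub
                if new not in seen:
                    seen.add(new)
                    queue.append(new)
                    if len(seen) >= max_subsets:
                        break
    candidates = [
        s for s in seen
        if s != start and _is_antichain(graph, s)
        and frozenset().union(*(cov[v] for v in s)) == target
    ]
    if not candidates:
        # no refinement below the root covers: fall back to the most
        # specific single covering node (possibly the root; IC pruning
        # removes it later if so)
        single = [v for v, g in cov.items() if g == target]
        best = max(single, key=lambda v: (stats.ic[v], v))
        logger.warning("no covering frontier below the root; using %s", best)
        return {best}
    best = min(
        candidates,
        key=lambda s: (
            -sum(stats.ic[v] for v in s) / len(s),
            len(s),
            tuple(sorted(s)),
        ),
    )
    assert frozenset().union(*(cov[v] for v in best)) == target
    return set(best)


def _covering_child_subsets(
    kids: list[str], cov: dict[str, frozenset[str]], needed: frozenset[str]
) -> list[frozenset[str]]:
    """Non-empty child subsets whose combined coverage includes ``needed``."""
    out = []
    for r in range(1, len(kids) + 1):
        for combo in combinations(kids, r):
            union = frozenset().union(*(cov[c] for c in combo))
            if needed <= union:
                out.append(frozenset(combo))
    return out


def pool_representatives(
    per_cluster: list[set[str]],
    graph: OntologyGraph,
    table: AnnotationTable,
) -> RepresentativeSet:
    """Merge per-cluster representatives; duplicates union their provenance."""
    provenance: dict[str, set[int]] = {}
    for idx, reps in enumerate(per_cluster):
        for t in reps:
            provenance.setdefault(t, set()).add(idx)
    coverage = {
        t: closure_coverage(graph, table, t) for t in provenance
    }
    return RepresentativeSet(
        reps=sorted(provenance), provenance=provenance, coverage=coverage
    )


def prune_low_ic(
    reps: RepresentativeSet, stats: TermStats, threshold: float
) -> RepresentativeSet:
    """Drop representatives with IC strictly below the threshold."""
    keep = {t for t in reps.reps if stats.ic[t] >= threshold}
    return reps._subset(keep)


def prune_hierarchical(
    reps: RepresentativeSet, graph: OntologyGraph, stats: TermStats
) -> RepresentativeSet:
    """Resolve hierarchically related representative pairs.

    An is_a ancestor of another representative is removed. For pairs related
    through a path involving part_of, the member covering more set genes is
    retained (tie: the more specific / higher-IC term, then the smaller
    identifier). Repeated until stable.
    """
    keep = set(reps.reps)
    changed = True
    while changed:
        changed = False
        for a in sorted(keep):
            isa_anc = graph.ancestors(a, frozenset({"is_a"})) & keep
            if isa_anc:
                keep -= isa_anc
                changed = True
                break
            mixed = (graph.ancestors(a) & keep) - isa_anc
            for b in sorted(mixed):
                ca, cb = len(reps.coverage[a]), len(reps.coverage[b])
                if ca != cb:
                    loser = a if ca < cb else b
                elif stats.ic[a] != stats.ic[b]:
                    loser = a if stats.ic[a] < stats.ic[b] else b
                else:
                    loser = max(a, b)
                keep.discard(loser)
                changed = True
                break
            if changed:
                break
    return reps._subset(keep)


def gene_support_threshold(n_genes: int) -> int:
    """Minimum genes each representative must cover, as a function of set size.

    floor(sqrt(|n/10 - 1|)) + 2 — grows slowly with the gene-set size so
    larger sets demand broader representatives.
    """
    if n_genes < 1:
        raise ValueError("gene set must contain at least one gene")
    return math.floor(math.sqrt(abs(n_genes / 10.0 - 1.0))) + 2


def filter_by_support(reps: RepresentativeSet, support: int) -> RepresentativeSet:
    """Drop representatives covering fewer than ``support`` set genes."""
    keep = {t for t in reps.reps if len(reps.coverage[t]) >= support}
    if not keep and reps.reps:
        logger.warning(
            "gene-support threshold %d removed every representative term", support
        )
    out = reps._subset(keep)
    out.support_threshold = support
    return out
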
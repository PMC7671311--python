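"""Final synthetic-term selection by weighted greedy set cover.

From the pruned representative terms, a minimal set of "synthetic" terms is
grown greedily: at each step the candidate maximizing

    score(t) = |coverage(t) - already covered| * w(t)

joins the result, where the weight

    w(t) = -log(annotated_genes_in_genome(t) / nb_genes_in_genome)
           / -log(annotated_genes_in_set(t) / nb_genes_in_set)

rewards terms that are rare genome-wide (the numerator is the classic
annotation-frequency information content) yet cover a large share of the
gene set (small denominator). Gene counts use annotation closure: a gene
counts for a term when annotated by it or any hierarchical descendant.

The module also computes the groupwise gene-set similarity (SimGIC style):
the IC mass of the terms shared by every gene's ancestor-closed annotation
set, over the IC mass of their union — 1.0 when all genes carry identical
annotations, 0.0 when they share nothing below the root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .annotations import AnnotationTable
from .ontology import OntologyGraph, TermStats
from .representatives import RepresentativeSet, closure_coverage

logger = logging.getLogger(__name__)

#: Cap for the degenerate Eq-denominator case (term covers the whole set).
EPSILON_DENOMINATOR = 1e-6


@dataclass
class SyntheticResult:
    synthetic: list[str]  # in greedy pick order
    weights: dict[str, float]
    covered_genes: set[str]
    uncovered_genes: set[str]
    coverage_fraction: float
    gene_set_similarity: float = float("nan")
    per_term: dict[str, dict] = field(default_factory=dict)
    degenerate_weights: list[str] = field(default_factory=list)


def term_weight(
    t: str,
    set_table: AnnotationTable,
    genome_table: AnnotationTable,
    graph: OntologyGraph,
) -> float:
    """Genome-rarity over set-rarity weight for one representative term."""
    n_genome = len(closure_coverage(graph, genome_table, t))
    if n_genome == 0:
        raise ValueError(f"term {t} annotates no gene in the genome scope")
    n_set = len(closure_coverage(graph, set_table, t) & set_table.genes)
    if n_set == 0:
        raise ValueError(f"term {t} annotates no gene in the gene set")
    numerator = -math.log(n_genome / genome_table.n_genes)
    ratio_set = n_set / set_table.n_genes
    if ratio_set >= 1.0:
        logger.warning(
            "term %s covers the whole gene set; weight capped at numerator/%g",
            t, EPSILON_DENOMINATOR,
        )
        return numerator / EPSILON_DENOMINATOR
    return numerator / -math.log(ratio_set)


def greedy_cover(
    coverage: dict[str, set[str]],
    weights: dict[str, float],
    ic: dict[str, float],
) -> tuple[list[str], set[str]]:
    """Core weighted greedy selection over arbitrary coverage sets.

    At each step picks the candidate maximizing |uncovered gain| * weight;
    ties break by larger gain, then higher IC, then smallest identifier.
    Stops when no candidate adds an uncovered element.
    """
    covered: set[str] = set()
    picked: list[str] = []
    remaining = set(coverage)
    while remaining:
        best, best_key = None, None
        for t in sorted(remaining):
            gain = len(coverage[t] - covered)
            key = (gain * weights[t], gain, ic[t])
            if best_key is None or key > best_key:
                best, best_key = t, key
        if best is None or best_key[1] == 0:
            break
        picked.append(best)
        covered |= coverage[best]
        remaining.discard(best)
    return picked, covered


def greedy_set_cover(
    reps: RepresentativeSet,
    set_table: AnnotationTable,
    genome_table: AnnotationTable,
    graph: OntologyGraph,
    stats: TermStats,
) -> SyntheticResult:
    """Pick synthetic terms greedily until no candidate adds a new gene."""
    weights: dict[str, float] = {}
    degenerate: list[str] = []
    for t in reps.reps:
        n_set = len(reps.coverage[t])
        weights[t] = term_weight(t, set_table, genome_table, graph)
        if n_set >= set_table.n_genes:
            degenerate.append(t)

    picked, covered = greedy_cover(reps.coverage, weights, stats.ic)

    all_coverable = set().union(*reps.coverage.values()) if reps.coverage else set()
    assert covered == all_coverable, "greedy stopped while gain was possible"

    annotated = set_table.genes
    per_term = {
        t: {
            "ic": stats.ic[t],
            "n_genes": len(reps.coverage[t]),
            "genes": sorted(reps.coverage[t]),
            "weight": weights[t],
            "pick_order": picked.index(t) + 1 if t in picked else None,
        }
        for t in reps.reps
    }
    return SyntheticResult(
        synthetic=picked,
        weights=weights,
        covered_genes=covered,
        uncovered_genes=annotated - covered,
        coverage_fraction=len(covered) / len(annotated) if annotated else 0.0,
        per_term=per_term,
        degenerate_weights=degenerate,
    )


def gene_set_similarity(
    set_table: AnnotationTable, graph: OntologyGraph, stats: TermStats
) -> float:
    """Groupwise similarity of the set's genes on ancestor-closed annotations.

    Returns NaN (with a warning) when fewer than two genes are annotated.
    """
    closed: list[set[str]] = []
    for g, ts in set_table.gene_to_terms.items():
        if not ts:
            continue
        ann = set(ts)
        for t in ts:
            ann |= graph.ancestors(t)
        closed.append(ann)
    if len(closed) < 2:
        logger.warning("gene-set similarity undefined for < 2 annotated genes")
        return float("nan")
    inter = set.intersection(*closed)
    union = set.union(*closed)
    denom = sum(stats.ic[t] for t in union)
    if denom == 0:
        logger.warning("all annotations carry zero IC; similarity undefined")
        return float("nan")
    return sum(stats.ic[t] for t in inter) / denom


def summarize(
    result: SyntheticResult,
    set_table: AnnotationTable,
    raw_gene_count: int,
) -> dict:
    """Gauge-level statistics: annotated %, covered %, similarity, per-term rows."""
    annotated = len([g for g, ts in set_table.gene_to_terms.items() if ts])
    return {
        "n_input_genes": raw_gene_count,
        "n_annotated_genes": annotated,
        "annotated_gene_pct": 100.0 * annotated / raw_gene_count if raw_gene_count else 0.0,
        "covered_gene_pct": 100.0 * len(result.covered_genes) / raw_gene_count
        if raw_gene_count else 0.0,
        "gene_set_similarity": result.gene_set_similarity,
        "n_synthetic_terms": len(result.synthetic),
        "synthetic_terms": list(result.synthetic),
        "per_term": [
            {"term": t, **result.per_term[t]}
            for t in sorted(
                result.per_term,
                key=lambda t: (
                    result.per_term[t]["pick_order"] is None,
                    result.per_term[t]["pick_order"] or 0,
                    t,
                ),
            )
        ],
    }
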
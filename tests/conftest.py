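"""Shared fixtures: the worked toy ontology/GAF and random-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from gosynth.annotations import AnnotationTable
from gosynth.ontology import OntologyGraph, compute_ic, parse_obo
from gosynth.simulate import worked_fixture

# worked-fixture shorthand
R, A, B, A1, A2, B1 = (
    "GO:0000001", "GO:0000002", "GO:0000003",
    "GO:0000004", "GO:0000005", "GO:0000006",
)


def graph_from_edges(
    edges: list[tuple[str, str, str]],
    extra_terms: tuple[str, ...] = (),
    namespace: str = "BP",
) -> OntologyGraph:
    """Build an OntologyGraph directly from (child, parent, relation) edges."""
    terms = set(extra_terms)
    for c, p, _ in edges:
        terms |= {c, p}
    hier_children = {c for c, p, r in edges if r in ("is_a", "part_of")}
    roots = sorted(terms - hier_children)
    assert len(roots) == 1, f"edge list must have one root, got {roots}"
    return OntologyGraph(
        terms=terms,
        name={t: t for t in terms},
        namespace={t: namespace for t in terms},
        edges=set(edges),
        obsolete=set(),
        alt_ids={},
        roots={namespace: roots[0]},
    )


def random_dag(
    seed: int, n_terms: int = 12, p_extra_parent: float = 0.3
) -> OntologyGraph:
    """A random rooted is_a/part_of DAG, independent of the package generator."""
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        p1 = terms[int(rng.integers(i))]
        rel = "part_of" if rng.random() < 0.2 else "is_a"
        edges.append((terms[i], p1, rel))
        if i >= 2 and rng.random() < p_extra_parent:
            p2 = terms[int(rng.integers(i))]
            if p2 != p1:
                edges.append((terms[i], p2, "is_a"))
    return graph_from_edges(edges)


def brute_force_ancestors(graph: OntologyGraph, t: str) -> set[str]:
    """Transitive closure by repeated one-step expansion (oracle)."""
    direct = {
        u: {p for c, p, r in graph.edges if c == u and r in ("is_a", "part_of")}
        for u in graph.terms
    }
    out: set[str] = set()
    frontier = set(direct[t])
    while frontier:
        out |= frontier
        frontier = set().union(*(direct[u] for u in frontier)) - out
    return out


def make_table(gene_to_terms: dict[str, set[str]], aspect="BP", scope="gene_set"):
    return AnnotationTable(aspect=aspect, gene_to_terms=gene_to_terms, scope=scope)


@pytest.fixture(scope="session")
def worked_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("worked")
    obo, gaf, genes = worked_fixture()
    (d / "worked.obo").write_text(obo)
    (d / "worked.gaf").write_text(gaf)
    (d / "worked_genes.txt").write_text(genes)
    return d / "worked.obo", d / "worked.gaf", d / "worked_genes.txt"


@pytest.fixture(scope="session")
def toy_graph(worked_paths):
    return parse_obo(str(worked_paths[0]))


@pytest.fixture(scope="session")
def toy_stats(toy_graph):
    return compute_ic(toy_graph, "BP")
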
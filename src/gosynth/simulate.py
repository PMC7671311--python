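"""Synthetic ontologies and annotation files for testing and simulation.

Generates OBO 1.2 ontologies (rooted DAGs with diamonds, part_of edges and
"regulation of" terms) and matching GAF 2.1 tables with a controllable
evidence-code mix, NOT qualifiers and deliberately redundant parent/child
annotation pairs — the failure modes the annotation filters exist to remove.
Everything is deterministic under the spec's seed.

``worked_fixture`` returns a small fixed six-term ontology and a ten-gene
GAF, checked into the package, whose information-content values are known in
closed form (ic(A) = ln 5, ic(A1) = ln 50, ic(B1) = ln 25) and which
exercises every annotation filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .ontology import OntologyGraph

_DEFAULT_EVIDENCE_MIX = {"IEA": 0.60, "EXP": 0.20, "IDA": 0.15, "ND": 0.05}


class FixtureSpecError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass
class FixtureSpec:
    """Parameters for one synthetic ontology + annotation pair."""

    n_terms: int = 60
    max_children: int = 6
    depth: int = 6
    part_of_fraction: float = 0.15
    extra_parent_rate: float = 0.2  # chance of a second parent (diamond)
    n_regulation_terms: int = 5
    n_genes: int = 40
    annotations_per_gene: tuple[int, int] = (2, 5)
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EVIDENCE_MIX)
    )
    not_qualifier_rate: float = 0.03
    redundant_pair_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_terms >= self.depth >= 1):
            raise FixtureSpecError(
                f"need n_terms >= depth >= 1, got {self.n_terms}, {self.depth}"
            )
        total = sum(self.evidence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureSpecError(f"evidence_mix sums to {total}, not 1")
        for code in ("ND", "IEA", "EXP"):
            if code not in self.evidence_mix:
                raise FixtureSpecError(f"evidence_mix must include {code}")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_ontology(spec: FixtureSpec) -> str:
    """OBO text for a rooted single-namespace DAG per the spec.

    The first ``depth`` non-root terms form a chain guaranteeing the target
    depth; remaining terms attach to random terms above the depth cap, with
    occasional second parents creating diamonds. Regulation terms sit under
    the root and carry a regulates-type edge to a random ordinary term.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_terms
    ids = [_term_id(i + 1) for i in range(n)]
    root = ids[0]
    depth = {root: 0}
    parents: dict[str, list[tuple[str, str]]] = {root: []}
    n_children = {root: 0}

    def _relation() -> str:
        return "part_of" if rng.random() < spec.part_of_fraction else "is_a"

    def _eligible(max_depth: int) -> list[str]:
        pool = [t for t in parents if depth[t] < max_depth
                and n_children[t] < spec.max_children]
        return pool or [t for t in parents if depth[t] < max_depth]

    chain_len = min(spec.depth, n - 1)
    prev = root
    for i in range(1, chain_len + 1):
        t = ids[i]
        parents[t] = [(prev, _relation())]
        depth[t] = i
        n_children[prev] += 1
        n_children[t] = 0
        prev = t

    for i in range(chain_len + 1, n):
        t = ids[i]
        pool = _eligible(spec.depth)
        p1 = pool[rng.integers(len(pool))]
        plist = [(p1, _relation())]
        d = depth[p1] + 1
        if rng.random() < spec.extra_parent_rate:
            pool2 = [u for u in _eligible(spec.depth) if u != p1]
            if pool2:
                p2 = pool2[rng.integers(len(pool2))]
                plist.append((p2, _relation()))
                d = max(d, depth[p2] + 1)
        parents[t] = plist
        depth[t] = d
        for p, _ in plist:
            n_children[p] += 1
        n_children[t] = 0

    reg_edges: dict[str, tuple[str, str]] = {}
    reg_ids = [_term_id(n + i + 1) for i in range(spec.n_regulation_terms)]
    ordinary = [t for t in ids if t != root]
    for rid in reg_ids:
        parents[rid] = [(root, "is_a")]
        n_children[root] += 1
        target = ordinary[rng.integers(len(ordinary))]
        rel = ["regulates", "positively_regulates", "negatively_regulates"][
            rng.integers(3)
        ]
        reg_edges[rid] = (target, rel)

    lines = ["format-version: 1.2", "ontology: synthetic-fixture", ""]
    for t in ids + reg_ids:
        lines.append("[Term]")
        lines.append(f"id: {t}")
        if t in reg_edges:
            lines.append(f"name: regulation of term {reg_edges[t][0]}")
        else:
            lines.append(f"name: term {t}")
        lines.append("namespace: biological_process")
        for p, rel in parents[t]:
            if rel == "is_a":
                lines.append(f"is_a: {p}")
            else:
                lines.append(f"relationship: {rel} {p}")
        if t in reg_edges:
            target, rel = reg_edges[t]
            lines.append(f"relationship: {rel} {target}")
        lines.append("")
    return "\n".join(lines)


def generate_gaf(graph: OntologyGraph, spec: FixtureSpec) -> str:
    """GAF 2.1 text annotating synthetic genes over the graph's terms.

    Evidence codes follow ``spec.evidence_mix``; NOT qualifiers and redundant
    gene-(term, ancestor) pairs are injected at the stated rates. Annotations
    may target regulation terms, exercising the replacement filter.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ns = sorted(graph.roots)[0]
    root = graph.roots[ns]
    candidates = sorted(graph.namespace_terms(ns) - {root})
    codes = sorted(spec.evidence_mix)
    probs = np.array([spec.evidence_mix[c] for c in codes])
    lo, hi = spec.annotations_per_gene

    lines = ["!gaf-version: 2.1"]

    def _emit(gene: str, term: str, evidence: str, qual: str) -> None:
        cols = ["SYNTH", f"S_{gene}", gene, qual, term, "SYNTH_REF:0000001",
                evidence, "", "P", f"{gene} protein", "", "protein",
                "taxon:0001", "20200101", "SYNTH", "", ""]
        lines.append("\t".join(cols))

    for gi in range(1, spec.n_genes + 1):
        gene = f"G{gi:04d}"
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(candidates))
        chosen = [candidates[i] for i in rng.choice(len(candidates), size=k,
                                                    replace=False)]
        for term in sorted(chosen):
            evidence = codes[int(rng.choice(len(codes), p=probs))]
            qual = "NOT" if rng.random() < spec.not_qualifier_rate else ""
            _emit(gene, term, evidence, qual)
        if chosen and rng.random() < spec.redundant_pair_rate:
            base = sorted(chosen)[int(rng.integers(len(chosen)))]
            ancestors = sorted(graph.ancestors(base) - {root})
            if ancestors:
                anc = ancestors[int(rng.integers(len(ancestors)))]
                evidence = codes[int(rng.choice(len(codes), p=probs))]
                _emit(gene, anc, evidence, "")
    return "\n".join(lines) + "\n"


def generate_gene_list(spec: FixtureSpec, fraction: float = 0.5) -> str:
    """A gene list drawing a deterministic subset of the generated genes."""
    rng = np.random.default_rng(spec.seed + 2)
    n_pick = max(2, int(round(fraction * spec.n_genes)))
    picks = sorted(rng.choice(spec.n_genes, size=min(n_pick, spec.n_genes),
                              replace=False) + 1)
    return "\n".join(f"G{i:04d}" for i in picks) + "\n"


def worked_fixture() -> tuple[str, str, str]:
    """The fixed six-term ontology, ten-gene GAF and gene list (OBO/GAF/text)."""
    pkg = resources.files("gosynth.data")
    return (
        (pkg / "worked.obo").read_text(),
        (pkg / "worked.gaf").read_text(),
        (pkg / "worked_genes.txt").read_text(),
    )
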
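"""End-to-end orchestration: from OBO + GAF + gene list to synthetic terms.

Each requested namespace runs independently through the full chain —
annotation cleaning, similarity matrix, average-linkage clustering with a
silhouette cut, representative selection and pruning, weighted greedy set
cover — and the per-namespace blocks are then merged (namespaces share no
terms, so merging is concatenation). The pipeline is deterministic end to
end: identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotations import (
    build_tables,
    filter_evidence,
    parse_gaf,
    replace_regulation,
)
from .clustering import (
    average_linkage,
    cophenetic_correlation,
    silhouette_cut,
    to_distance,
)
from .ontology import (
    compute_ic,
    ic_percentile_threshold,
    most_informative_parent_tree,
    parse_obo,
)
from .representatives import (
    TermCluster,
    filter_by_support,
    gene_support_threshold,
    majority_representative,
    msrt,
    pool_representatives,
    prune_hierarchical,
    prune_low_ic,
)
from .similarity import similarity_matrix
from .synthesis import gene_set_similarity, greedy_set_cover, summarize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    obo_path: str
    gaf_path: str
    gene_list_path: str
    aspects: tuple[str, ...] = ("BP",)
    include_iea: bool = True
    measure: str = "aic"
    gene_support: int | str = "auto"
    tolerance: str = "medium"
    output_dir: str | None = None
    dump_similarity: bool = False
    dump_clusters: bool = False
    max_subsets: int = 5000

    def __post_init__(self) -> None:
        if not self.aspects:
            raise ValueError("at least one namespace must be requested")


@dataclass
class RunReport:
    config: dict
    aspects: dict
    merged: dict
    version: str = field(default="")

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "aspects": self.aspects,
             "merged": self.merged, "version": self.version},
            indent=2, sort_keys=True, allow_nan=True,
        )


def _read_gene_list(path: str) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines()]
    genes = [g for g in genes if g]
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    return genes


def run_gsan(config: RunConfig) -> RunReport:
    """Run the full workflow for every requested namespace and merge."""
    graph = parse_obo(config.obo_path)
    records = parse_gaf(config.gaf_path, graph)
    gene_list = _read_gene_list(config.gene_list_path)

    aspect_blocks: dict[str, dict] = {}
    for ns in config.aspects:
        try:
            aspect_blocks[ns] = _run_aspect(config, graph, records, gene_list, ns)
        except Exception as exc:
            raise RuntimeError(f"[{ns}] pipeline failed: {exc}") from exc

    merged_synthetic: list[str] = []
    merged_reps: list[dict] = []
    for ns in config.aspects:
        block = aspect_blocks[ns]
        merged_synthetic.extend(block["summary"].get("synthetic_terms", []))
        merged_reps.extend(block.get("representatives", []))
    merged = {
        "synthetic_terms": merged_synthetic,
        "n_synthetic_terms": len(merged_synthetic),
        "representatives": merged_reps,
    }
    return RunReport(
        config={**asdict(config), "aspects": list(config.aspects)},
        aspects=aspect_blocks,
        merged=merged,
        version=__version__,
    )


def _run_aspect(config, graph, records, gene_list, ns: str) -> dict:
    stats = compute_ic(graph, ns)
    threshold = ic_percentile_threshold(stats, config.tolerance)

    n_raw = len(records)
    recs = filter_evidence(records, include_iea=config.include_iea)
    n_evidence = len(recs)
    recs = replace_regulation(graph, recs)
    n_regulation = len(recs)

    genome, geneset = build_tables(
        recs, graph, ns, gene_list, stats=stats, threshold=threshold
    )
    counters = {
        "records_raw": n_raw,
        "records_after_evidence_filter": n_evidence,
        "records_after_regulation_replacement": n_regulation,
        "genome_annotated_genes": genome.n_genes,
        "set_annotated_genes": geneset.n_genes,
        "ic_threshold": threshold,
    }
    if geneset.n_genes == 0:
        return {"status": "no_annotation", "counters": counters, "summary": {}}

    terms = sorted(geneset.terms)
    diagnostics: dict = {}
    if len(terms) == 1:
        clusters = [set(terms)]
        diagnostics.update(k=1, asw=float("nan"), cophenetic=float("nan"))
        sim = None
    else:
        sim = similarity_matrix(config.measure, graph, stats, terms)
        dist = to_distance(sim)
        dendro = average_linkage(dist, terms)
        clustering = silhouette_cut(dendro, dist)
        clusters = clustering.clusters
        diagnostics.update(
            k=clustering.k,
            asw=clustering.asw,
            cophenetic=cophenetic_correlation(dendro, dist),
        )

    per_cluster: list[set[str]] = []
    cluster_of: dict[str, int] = {}
    for idx, cl_terms in enumerate(clusters):
        cluster = TermCluster.from_table(cl_terms, geneset)
        for t in cl_terms:
            cluster_of[t] = idx
        rep = majority_representative(cluster, geneset, graph, stats)
        reps = {rep} if rep is not None else msrt(
            graph, stats, cluster, geneset, max_subsets=config.max_subsets
        )
        per_cluster.append(reps)

    pooled = pool_representatives(per_cluster, graph, geneset)
    n_pooled = len(pooled.reps)
    pooled = prune_low_ic(pooled, stats, threshold)
    n_ic = len(pooled.reps)
    pooled = prune_hierarchical(pooled, graph, stats)
    n_hier = len(pooled.reps)
    if config.gene_support == "auto":
        support = gene_support_threshold(len(gene_list))
    else:
        support = int(config.gene_support)
    pooled = filter_by_support(pooled, support)
    counters.update(
        representatives_pooled=n_pooled,
        representatives_after_ic_pruning=n_ic,
        representatives_after_hierarchy_pruning=n_hier,
        representatives_after_support_filter=len(pooled.reps),
        gene_support=support,
    )

    result = greedy_set_cover(pooled, geneset, genome, graph, stats)
    result.gene_set_similarity = gene_set_similarity(geneset, graph, stats)
    summary = summarize(result, geneset, raw_gene_count=len(gene_list))
    summary["gene_set_similarity"] = result.gene_set_similarity

    rep_rows = [
        {
            "term_id": t,
            "name": graph.name[t],
            "aspect": ns,
            "ic": stats.ic[t],
            "weight": result.weights[t],
            "n_genes": len(pooled.coverage[t]),
            "genes": "|".join(sorted(pooled.coverage[t])),
            "cluster": ",".join(str(c) for c in sorted(pooled.provenance[t])),
            "synthetic": t in result.synthetic,
        }
        for t in pooled.reps
    ]
    tree = _tree_json(graph, stats, pooled, result)
    block = {
        "status": "ok",
        "counters": counters,
        "diagnostics": diagnostics,
        "clusters": {t: c for t, c in sorted(cluster_of.items())},
        "summary": summary,
        "representatives": rep_rows,
        "tree": tree,
        "degenerate_weights": result.degenerate_weights,
    }
    if config.dump_similarity and sim is not None:
        block["similarity_matrix"] = {
            "terms": sim.terms, "values": sim.values.tolist(),
            "measure": sim.measure,
        }
    return block


def _tree_json(graph, stats, pooled, result) -> dict:
    """Most-informative-parent tree over the representatives, genes as leaves."""
    if not pooled.reps:
        return {}
    parent = most_informative_parent_tree(graph, stats, pooled.reps)
    children: dict[str | None, list[str]] = {}
    for t, p in parent.items():
        children.setdefault(p, []).append(t)

    def _node(t: str) -> dict:
        node = {
            "id": t,
            "name": graph.name[t],
            "ic": stats.ic[t],
            "depth": stats.depth[t],
            "synthetic": t in result.synthetic,
            "children": [_node(c) for c in sorted(children.get(t, []))],
        }
        if t in pooled.coverage:
            node["genes"] = sorted(pooled.coverage[t])
        return node

    roots = sorted(children.get(None, []))
    return _node(roots[0]) if len(roots) == 1 else {
        "id": "forest", "children": [_node(r) for r in roots]
    }


REP_CSV_COLUMNS = [
    "term_id", "name", "aspect", "ic", "weight", "n_genes", "genes",
    "cluster", "synthetic",
]


def write_outputs(report: RunReport, output_dir: str) -> list[Path]:
    """Write the representative CSV, summary JSON and a text log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "representative_terms.csv"
    df = pd.DataFrame(report.merged["representatives"], columns=REP_CSV_COLUMNS)
    df.to_csv(csv_path, index=False)
    written.append(csv_path)

    json_path = out / "summary.json"
    json_path.write_text(report.to_json() + "\n")
    written.append(json_path)

    log_path = out / "run.log"
    lines = [f"gosynth {report.version}"]
    for ns, block in report.aspects.items():
        lines.append(f"[{ns}] status={block['status']}")
        for k, v in block.get("counters", {}).items():
            lines.append(f"[{ns}] {k}={v}")
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written
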
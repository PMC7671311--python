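"""Generate a randomized ontology/annotation fixture and run the pipeline.

The generator emits a rooted DAG with is_a, part_of and regulatory edges
plus a GAF-style annotation file with a configurable evidence mix, NOT
qualifiers and redundant ancestor annotations — the failure modes the
filters exist to handle. Everything is seed-deterministic.
"""

import tempfile
from pathlib import Path

from gosynth import RunConfig, parse_obo, run_gsan
from gosynth.simulate import (
    FixtureSpec,
    generate_gaf,
    generate_gene_list,
    generate_ontology,
)

spec = FixtureSpec(n_terms=60, n_genes=40, seed=7)

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    (d / "sim.obo").write_text(generate_ontology(spec))
    graph = parse_obo(str(d / "sim.obo"))
    (d / "sim.gaf").write_text(generate_gaf(graph, spec))
    (d / "genes.txt").write_text(generate_gene_list(spec))

    print(f"generated {len(graph.terms)} terms, {len(graph.edges)} edges")

    report = run_gsan(RunConfig(
        obo_path=str(d / "sim.obo"),
        gaf_path=str(d / "sim.gaf"),
        gene_list_path=str(d / "genes.txt"),
    ))

block = report.aspects["BP"]
summary = block["summary"]
diag = block["diagnostics"]
print(f"clusters: k={diag['k']}, silhouette={diag['asw']:.3f}")
print(f"synthetic terms: {summary['n_synthetic_terms']}")
print(f"covered genes: {summary['covered_gene_pct']:.1f}% of the list")
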
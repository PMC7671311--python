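"""Parse the bundled worked ontology and inspect term information content.

The information content of a term is derived from its ancestors' descendant
counts: specific terms deep in the graph score high, the root scores zero.
"""

import tempfile
from pathlib import Path

from gosynth import compute_ic, ic_percentile_threshold, parse_obo
from gosynth.simulate import worked_fixture

obo_text, _, _ = worked_fixture()
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "worked.obo"
    path.write_text(obo_text)
    graph = parse_obo(str(path))

stats = compute_ic(graph, "BP")

print(f"{'term':<12} {'name':<22} {'depth':>5} {'IC':>8}")
for term in sorted(graph.namespace_terms("BP")):
    print(f"{term:<12} {graph.name[term]:<22} "
          f"{stats.depth[term]:>5} {stats.ic[term]:>8.4f}")

threshold = ic_percentile_threshold(stats, "medium")
print(f"\nmedium-tolerance IC threshold (25th percentile): {threshold:.4f}")
print("terms at or below this threshold are treated as too general.")
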
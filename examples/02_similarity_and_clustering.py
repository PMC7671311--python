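"""Compare annotation terms pairwise and group them by average linkage.

Builds the aggregate-IC similarity matrix for the worked ontology's
non-root terms, converts it to a distance, clusters with UPGMA, and lets
the average silhouette width pick the number of clusters.
"""

import tempfile
from pathlib import Path

import numpy as np

from gosynth import (
    average_linkage,
    compute_ic,
    parse_obo,
    silhouette_cut,
    similarity_matrix,
    to_distance,
)
from gosynth.simulate import worked_fixture

obo_text, _, _ = worked_fixture()
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "worked.obo"
    path.write_text(obo_text)
    graph = parse_obo(str(path))

stats = compute_ic(graph, "BP")
terms = sorted(graph.namespace_terms("BP") - {stats.root})

sim = similarity_matrix("aic", graph, stats, terms)
print("aggregate-IC similarity matrix:")
with np.printoptions(precision=3, suppress=True):
    print(sim.values)

dist = to_distance(sim)
dendro = average_linkage(dist, terms)
result = silhouette_cut(dendro, dist)

print(f"\nchosen k = {result.k}, average silhouette width = {result.asw:.3f}")
for i, cluster in enumerate(result.clusters):
    names = ", ".join(graph.name[t] for t in sorted(cluster))
    print(f"  cluster {i}: {names}")
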
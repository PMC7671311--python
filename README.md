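# gosynth

Synthetic annotation of gene sets against a structured ontology, without
statistical enrichment tests.

## The problem

Given a gene set of interest (say, the genes differentially expressed in an
experiment) and a corpus of curated annotations mapping genes to terms of a
directed-acyclic ontology (such as the Gene Ontology), the usual question is:
*which biological concepts describe this gene set?* Enrichment analysis
answers it with per-term hypothesis tests, which over-reports redundant
general terms and fragments the signal across near-synonymous specific ones.

`gosynth` instead builds a small, non-redundant set of **synthetic terms**
that jointly *cover* the gene set:

1. **Information content (IC).** Every term gets an IC derived from the
   ontology topology alone: `IC(t) = −ln p(t)` with
   `p(t) = Π_{a ∈ Anc(t)} p(a)/|Desc(a)|`, accumulated in log space. Specific
   terms score high; the root scores zero.
2. **Annotation filtering.** GAF 2.1 annotations are cleaned: `NOT`-qualified
   records removed, genes annotated only by "no data" (ND) evidence dropped,
   electronically inferred (IEA) records optionally excluded, regulation
   terms replaced by the process they regulate, per-gene ancestors of more
   specific annotations removed, and terms at or below an IC percentile
   threshold discarded as uninformative.
3. **Clustering.** Surviving terms are compared pairwise (five semantic
   similarity measures available), clustered with average-linkage
   agglomeration, and the dendrogram is cut at the number of clusters that
   maximizes the average silhouette width.
4. **Representative selection.** Each cluster is summarized either by a term
   annotating more than 70 % of its genes or, failing that, by the
   highest-mean-IC antichain of (possibly more general) terms that still
   covers every gene of the cluster.
5. **Synthesis.** Representatives pass IC, hierarchy and gene-support
   pruning, then a weighted greedy set cover picks the final synthetic
   terms, weighting each term by how much rarer it is genome-wide than
   inside the gene set.

All stages are deterministic: the same inputs produce byte-identical outputs.

## Quick start

The package ships a tiny worked example (six terms, ten genes). Run it from
the command line:

```sh
python examples/03_full_annotation_run.py
```

which prints:

```
records_raw: 14
records_after_evidence_filter: 12
set_annotated_genes: 8
gene_support: 2
...
synthetic terms (3):
  GO:0000005  weight=1.000  genes=3
  GO:0000006  weight=1.000  genes=3
  GO:0000004  weight=1.000  genes=2
annotated genes: 80.0% of the list
covered genes:   80.0% of the list
```

Two of the fourteen raw annotation records are filtered (one `NOT`
qualifier, one ND-only pair), two genes lose all annotation, and the three
specific leaf terms cover all eight remaining genes.

Equivalently through the CLI on your own files:

```sh
gosynth run --obo go.obo --gaf annotations.gaf --genes genes.txt \
    --out results/ --measure aic --tolerance medium
```

Outputs land in `results/`: `representative_terms.csv` (one row per
representative with IC, weight and supporting genes), `summary.json` (the
full machine-readable report) and `run.log`.

Generate a randomized test fixture with `gosynth fixtures --seed 7 --out fx/`.

As a library:

```python
from gosynth import RunConfig, run_gsan

report = run_gsan(RunConfig(obo_path="go.obo", gaf_path="anno.gaf",
                            gene_list_path="genes.txt", aspects=("BP", "MF")))
print(report.merged["synthetic_terms"])
```

The `examples/` directory walks through each stage separately: ontology
parsing and IC (`01`), similarity and clustering (`02`), the full run
(`03`), and the fixture generator (`04`).

## Testing

```sh
python -m pytest -q tests/
```

The suite (~450 tests) checks every numeric routine against an independent
implementation: IC against the literal probability product, UPGMA against
scipy, silhouettes against scikit-learn, representative antichains and set
covers against exhaustive enumeration, plus hand-derived closed-form values
on the worked fixture.

## Documentation

See [`docs/methods.md`](docs/methods.md) for the model, parameter defaults
and their rationale, numerical conventions, and known limitations.
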
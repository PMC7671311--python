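# Methods

## Model and notation

The input is a rooted directed acyclic graph (DAG) of terms with typed
edges. Hierarchical relations (`is_a`, `part_of`) define ancestry;
regulatory relations (`regulates`, `positively_regulates`,
`negatively_regulates`) do not. Each ontology namespace (biological
process, molecular function, cellular component) must have exactly one root
from which every term in the namespace is reachable, and each namespace is
processed independently. `Anc(t)` and `Desc(t)` denote the *exclusive*
ancestor and descendant closures over hierarchical edges (a term is not its
own ancestor); where a computation needs the inclusive closure it says so.

Annotations follow the GAF 2.1 format (17 tab-separated columns, `!`
comments). Gene identity is the upper-cased DB Object Symbol; the same
symbol in different letter cases is one gene.

## Information content

For each term, with the root given `p(root) = 1`:

```
p(t)  = Π_{a ∈ Anc(t)} p(a) / |Desc(a)|        (inclusive of the root)
IC(t) = −ln p(t)
```

The product is accumulated in log space in topological order:
`log p(t) = Σ_a [log p(a) − log|Desc(a)|]`. On deep, heavily multi-parented
graphs `p(t)` can underflow double precision to 0.0 while `IC(t)` remains
finite and exact — this is why the log-space formulation is not optional.
Natural logarithms are used throughout.

### IC percentile threshold

Terms whose IC falls at or below a percentile of the namespace-wide IC
distribution (root included) are considered too general. The tolerance
levels map to percentiles **none → 1, low → 10, medium → 25 (default),
hard → 50**, computed with linear interpolation (`numpy.percentile`,
`method="linear"`). Filtering is strict: a term survives only if
`IC > threshold`; representatives are kept when `IC ≥ threshold`.

## Annotation filtering

Applied in order, each step idempotent:

1. Records with a `NOT` qualifier are removed.
2. Optionally (default off), IEA-evidenced records are removed.
3. For each (gene, term, aspect), if ND ("no biological data") is the *only*
   evidence, the pair is removed; if other evidence exists, the ND record is
   dropped and the pair kept.
4. Regulation terms are replaced by the term they regulate, followed to a
   fixpoint (regulation-of-regulation chains collapse to the regulated
   process); a regulatory cycle is an input error.
5. Per gene, any annotated term that is a hierarchical ancestor of another
   annotated term of the same gene is removed (most-specific retention).
6. Terms at or below the IC threshold are removed (strict, as above).

Two annotation tables are maintained with identical cleaning: the *genome*
table (all annotated genes) and the *gene set* table (the user's list,
matched case-insensitively). Gene counts are always recomputed after
filtering — a gene with zero surviving terms does not count as annotated.

## Term similarity

Five pairwise measures, all in [0, 1], all symmetric, dispatched by name.
`MICA(t1, t2)` is the common ancestor-or-self with maximal IC (ties broken
by lexicographically smallest identifier).

- `resnik_norm` = IC(MICA) / max_IC over the namespace.
- `lin` = 2·IC(MICA) / (IC(t1) + IC(t2)); 0 when both ICs are 0.
- `nunivers` = IC(MICA) / max(IC(t1), IC(t2)).
- `aic` — aggregate IC: each term contributes semantic weights
  `SW(t) = 1/(1 + e^(−1/IC(t)))` summed over its inclusive ancestors, with
  `SW(root) = 1` pinned (the limit of the formula as IC → 0 is 1/2; the
  root is defined to carry full weight so identical terms score 1);
  similarity is twice the shared-ancestor weight over the sum of both
  terms' totals.
- `distance` = 1 − d/(2·max_depth), where d is the shortest
  common-ancestor path (minimum over common ancestors of the sum of the two
  upward hop counts). This measure is **provisional**: the source
  description is ambiguous about the path normalization, and the CLI warns
  when it is selected.

Identical terms score 1.0 under every measure except `resnik_norm`, which
keeps its IC normalization (the root paired with itself scores 0).

## Clustering

Distance = 1 − similarity. Agglomeration is average linkage (UPGMA),
implemented in-package so that ties are broken deterministically by the
lexicographically smallest member sets; `scipy.cluster.hierarchy.linkage`
serves as the test oracle on tie-free matrices. The tree is cut at every
k from 2 to n−1 (and k = n when n ≤ 3) and scored by average silhouette
width (Rousseeuw; singletons score 0); the maximizing k wins, smallest k on
ties. The cophenetic correlation of the dendrogram is reported as a
diagnostic (NaN when all distances are equal).

## Representative selection

Per cluster:

- **Majority rule.** If some cluster term (via its inclusive descendant
  closure) annotates strictly more than 70 % of the cluster's genes, the
  best such term represents the cluster alone (ties: larger coverage, then
  higher IC, then smaller identifier).
- **Frontier search (otherwise).** Over the sub-DAG induced by the cluster
  terms and their ancestors, a breadth-first refinement starting at the
  namespace root repeatedly replaces a node by a subset of its children,
  keeping only states that still cover every cluster gene (rolled-up
  coverage). Child subsets are enumerated exhaustively for nodes with ≤ 12
  children; wider nodes contribute only the full child set. Among all
  covering antichains encountered, the winner maximizes mean IC, then has
  fewer terms, then the lexicographically smallest term tuple. An
  exhaustive antichain enumeration is the test oracle. Exact coverage of
  the cluster's genes is an asserted invariant.

Pooled representatives are then pruned:

1. IC pruning: keep only `IC ≥ threshold` (the root is always removed).
2. Hierarchy pruning: an `is_a` ancestor of another representative is
   removed; for pairs related through a `part_of` path, the one covering
   more genes is kept (ties: higher IC, then smaller identifier).
3. Gene support: with gene-list size n, representatives covering fewer than
   `⌊√|n/10 − 1|⌋ + 2` genes are removed (10 genes → 2, 84 → 4, 250 → 6;
   non-decreasing beyond n = 10). `--gene-support auto` (default) derives n
   from the raw input gene list; an integer overrides it.

## Synthetic term selection

Each surviving representative t gets a rarity weight

```
w(t) = −log(n_genome(t)/N_genome) / −log(n_set(t)/N_set)
```

with gene counts rolled up over descendants. If the set-ratio is ≥ 1 (the
term covers the whole currently annotated set) the denominator is capped at
ε = 10⁻⁶ and a warning is emitted. A greedy set cover then repeatedly picks
the term maximizing `uncovered-gain × w(t)` (ties: larger raw gain, then
higher IC, then smaller identifier) until no term adds coverage. The
unweighted special case coincides with textbook greedy set cover and hence
inherits the (1 + ln m)·OPT guarantee, which the tests verify against
exhaustive optima.

The final report includes the SimGIC groupwise similarity of the gene set:
the IC-sum of the intersection over the IC-sum of the union of the genes'
ancestor-closed annotation sets (1 for identically annotated genes, 0 for
genes on disjoint branches, NaN when fewer than two genes are annotated).

## Fixture generator

`gosynth.simulate` produces seed-deterministic OBO/GAF/gene-list triples:
a rooted DAG built depth-first to a target depth, extra parents to create
diamonds, a configurable `part_of` fraction, regulation terms attached
under the root with a regulatory edge to a random ordinary term; and
annotations with a configurable evidence mix (default 60 % IEA, 20 % EXP,
15 % IDA, 5 % ND), `NOT`-qualifier injection and redundant
ancestor-annotation injection. It emulates the *shape* of real corpora
(DAG topology, evidence codes, the failure modes the filters target), not
their biology: term names are synthetic, gene symbols are `G0001…`, and
annotation placement is uniform rather than biased toward well-studied
genes.

## Numerical and determinism conventions

- Natural logs everywhere; IC computed in log space (see above).
- All set iterations are over sorted containers; every tie-break is pinned
  (documented per stage above). Two runs on the same inputs produce
  byte-identical CSV/JSON/log outputs.
- JSON output uses sorted keys; NaN is serialized as JavaScript `NaN`
  (Python `json` default), consumed back by the same module.
- Percentiles via `numpy.percentile` linear interpolation.

## Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| `measure` | `aic` | uses full ancestor topology, no corpus frequencies needed |
| `tolerance` | `medium` (25th pct) | balances generality filtering against annotation loss |
| `include_iea` | true | IEA dominates most corpora; excluding it is the opt-in |
| `gene_support` | `auto` | scales the support floor with gene-list size |
| majority cutoff | 0.70 (strict >) | a single term must clearly dominate its cluster |
| `max_subsets` | 5000 child subsets per node (≤ 12 children enumerated) | keeps frontier search exact on realistic clusters, bounded on pathological ones |
| ε (weight cap) | 10⁻⁶ | keeps whole-set terms usable with a large finite weight |

## Open design decisions and limitations

- The `distance` measure's path normalization is a best-effort reading of
  an ambiguous description; it is flagged provisional in the CLI.
- The frontier search is exact only while every expanded node has ≤ 12
  children; beyond that it degrades gracefully (full child set only) and
  may miss the optimal antichain, though coverage exactness is still
  asserted. A most-specific single covering term is the warned fallback.
- Aspects are processed independently; the merged report concatenates
  per-aspect results and performs no cross-aspect deduplication.
- The IC model is purely topological; corpus-frequency IC variants are out
  of scope.
- GAF parsing targets version 2.1; 2.2's qualifier vocabulary is accepted
  only insofar as `NOT` is still detected.
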
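"""GAF 2.1 parsing and removal of uninformative annotations.

Four cleaning rules are applied to the raw gene-term associations before any
similarity or clustering step:

1. evidence filtering — records negated with the ``NOT`` qualifier are
   dropped, gene-term pairs supported exclusively by the ``ND`` (no
   biological data) evidence code are dropped, and ``IEA`` (electronic)
   records are optionally excluded;
2. regulation replacement — an annotation to a "regulation of X" term is
   re-targeted to X itself, iterated to fixpoint so chains of regulation
   collapse onto the regulated process;
3. hierarchical redundancy — when a gene is annotated by two hierarchically
   related terms, only the most specific one is kept;
4. incomplete information — terms whose IC does not exceed a percentile
   threshold of the namespace IC distribution are too general to be
   informative and are dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

from .ontology import (
    NAMESPACE_OF_ASPECT,
    OntologyGraph,
    TermStats,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

GAF_COLUMNS = [
    "db", "object_id", "symbol", "qualifier", "term", "reference",
    "evidence", "with_from", "aspect", "name", "synonym", "object_type",
    "taxon", "date", "assigned_by", "extension", "gene_product_form",
]


class GafError(ValueError):
    """Raised for unusable GAF input."""


@dataclass(frozen=True)
class GafRecord:
    db: str
    object_id: str
    symbol: str
    qualifiers: frozenset[str]
    term: str
    evidence: str
    aspect: str
    synonyms: str = ""
    taxon: str = ""

    @property
    def gene(self) -> str:
        """Case-insensitive gene key (DB object symbol)."""
        return self.symbol.upper()


def parse_gaf(path: str, graph: OntologyGraph | None = None) -> list[GafRecord]:
    """Read a 17-column GAF 2.1 file into records.

    Comment lines start with ``!``; malformed data lines are dropped and
    counted. When ``graph`` is given, term identifiers are resolved through
    its alt_id map at parse time and records hitting obsolete or unknown
    terms are dropped (with a logged count).
    """
    bad = 0

    def _on_bad(line: list[str]) -> None:
        nonlocal bad
        bad += 1
        return None

    try:
        df = pd.read_csv(
            path, sep="\t", comment="!", header=None, names=GAF_COLUMNS,
            dtype=str, keep_default_na=False, engine="python",
            on_bad_lines=_on_bad,
        )
    except OSError as exc:
        raise GafError(f"cannot read GAF file {path}: {exc}") from exc
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=GAF_COLUMNS)

    records: list[GafRecord] = []
    unresolved = 0
    for row in df.itertuples(index=False):
        if not (row.symbol and row.term and row.evidence and row.aspect):
            bad += 1
            continue
        term = row.term
        if graph is not None:
            try:
                term = graph.resolve(term)
            except UnknownTermError:
                unresolved += 1
                continue
        quals = frozenset(q for q in row.qualifier.split("|") if q)
        records.append(GafRecord(
            db=row.db, object_id=row.object_id, symbol=row.symbol,
            qualifiers=quals, term=term, evidence=row.evidence,
            aspect=row.aspect, synonyms=row.synonym, taxon=row.taxon,
        ))
    if bad:
        logger.warning("dropped %d malformed GAF lines", bad)
    if unresolved:
        logger.warning("dropped %d records with unresolvable/obsolete terms", unresolved)
    if not records:
        raise GafError(f"no valid annotation records in {path}")
    return records


def filter_evidence(records: list[GafRecord], include_iea: bool = True) -> list[GafRecord]:
    """Drop NOT-qualified records and ND-exclusive gene-term pairs.

    ND exclusivity is judged per (gene, term) pair across all its records.
    If ``include_iea`` is false, IEA records are removed before the
    exclusivity test. Surviving duplicates collapse to one record per pair.
    """
    kept = [r for r in records if "NOT" not in r.qualifiers]
    if not include_iea:
        kept = [r for r in kept if r.evidence != "IEA"]
    by_pair: dict[tuple[str, str, str], list[GafRecord]] = defaultdict(list)
    for r in kept:
        by_pair[(r.gene, r.term, r.aspect)].append(r)
    out: list[GafRecord] = []
    for pair_records in by_pair.values():
        if all(r.evidence == "ND" for r in pair_records):
            continue
        out.append(pair_records[0])
    return out


def replace_regulation(graph: OntologyGraph, records: list[GafRecord]) -> list[GafRecord]:
    """Re-target annotations on regulation terms to the regulated terms.

    A gene regulating a process is taken to be involved in that process.
    Applied iteratively so regulation-of-regulation chains collapse;
    duplicates created by remapping are merged.
    """
    resolved: dict[str, str] = {}

    def _fixpoint(term: str) -> str:
        if term in resolved:
            return resolved[term]
        seen: list[str] = []
        t = term
        while True:
            if t in seen:
                raise ValueError(f"regulates cycle through {t}")
            seen.append(t)
            target = graph.regulation_target(t)
            if target is None:
                break
            t = target
        for s in seen:
            resolved[s] = t
        return t

    out: dict[tuple[str, str, str], GafRecord] = {}
    for r in records:
        target = _fixpoint(r.term)
        r2 = r if target == r.term else replace(r, term=target)
        out.setdefault((r2.gene, r2.term, r2.aspect), r2)
    return list(out.values())


@dataclass
class AnnotationTable:
    """Bidirectional gene-term mapping for one namespace and scope.

    ``n_genes`` counts genes currently carrying at least one term; genes
    emptied by a filter drop out of it (they are accounted as unannotated in
    the run summary, which uses the raw input gene count).
    """

    aspect: str  # namespace code BP/MF/CC
    gene_to_terms: dict[str, set[str]]
    scope: str  # "genome" | "gene_set"
    n_genes: int = field(init=False)
    term_to_genes: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_to_terms = {g: set(ts) for g, ts in self.gene_to_terms.items() if ts}
        self.n_genes = len(self.gene_to_terms)
        self._rebuild()

    def _rebuild(self) -> None:
        t2g: dict[str, set[str]] = defaultdict(set)
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                t2g[t].add(g)
        self.term_to_genes = dict(t2g)

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def _with(self, gene_to_terms: dict[str, set[str]]) -> "AnnotationTable":
        return AnnotationTable(
            aspect=self.aspect, gene_to_terms=gene_to_terms, scope=self.scope,
        )


def remove_hierarchical_redundancy(
    graph: OntologyGraph, table: AnnotationTable
) -> AnnotationTable:
    """Keep only each gene's most specific terms.

    For each gene, a term that is a hierarchical ancestor of another term
    annotating the same gene is removed.
    """
    new: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    for g, ts in table.gene_to_terms.items():
        redundant: set[str] = set()
        for t in ts:
            if t not in anc_cache:
                anc_cache[t] = graph.ancestors(t)
            redundant |= anc_cache[t] & ts
        new[g] = ts - redundant
    return table._with(new)


def filter_incomplete(
    table: AnnotationTable, stats: TermStats, threshold: float
) -> AnnotationTable:
    """Drop annotations to terms whose IC does not exceed ``threshold``.

    Strictly "higher than": a term with IC equal to the threshold is removed.
    Genes left without terms stay in the ``n_genes`` denominator as
    unannotated.
    """
    new = {
        g: {t for t in ts if stats.ic.get(t, 0.0) > threshold}
        for g, ts in table.gene_to_terms.items()
    }
    return table._with(new)


def build_tables(
    records: list[GafRecord],
    graph: OntologyGraph,
    aspect: str,
    gene_list: list[str] | None = None,
    stats: TermStats | None = None,
    threshold: float | None = None,
) -> tuple[AnnotationTable, AnnotationTable | None]:
    """Assemble genome- and gene-set-scope tables for one namespace.

    ``records`` should already have passed evidence filtering and regulation
    replacement. Both tables then go through hierarchical-redundancy removal
    and, when ``stats``/``threshold`` are given, the incomplete-information
    filter. Gene-list matching is case-insensitive on the GAF symbol column.
    """
    ns = aspect if aspect in NAMESPACE_OF_ASPECT.values() else NAMESPACE_OF_ASPECT[aspect]
    letter = {v: k for k, v in NAMESPACE_OF_ASPECT.items()}[ns]

    g2t: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.aspect == letter:
            g2t[r.gene].add(r.term)
    genome = AnnotationTable(aspect=ns, gene_to_terms=dict(g2t), scope="genome")

    gene_set: AnnotationTable | None = None
    if gene_list is not None:
        wanted = {g.upper() for g in gene_list}
        matched = {g: ts for g, ts in g2t.items() if g in wanted}
        missing = sorted(wanted - set(matched))
        if not matched:
            raise GafError(
                f"no gene-list symbol found in the GAF for {ns}; "
                f"unmatched: {missing}"
            )
        if missing:
            logger.warning("%d gene-list symbols not annotated in %s: %s",
                           len(missing), ns, missing)
        gene_set = AnnotationTable(aspect=ns, gene_to_terms=matched, scope="gene_set")

    def _clean(t: AnnotationTable) -> AnnotationTable:
        t = remove_hierarchical_redundancy(graph, t)
        if stats is not None and threshold is not None:
            t = filter_incomplete(t, stats, threshold)
        return t

    genome = _clean(genome)
    if gene_set is not None:
        gene_set = _clean(gene_set)
    return genome, gene_set
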
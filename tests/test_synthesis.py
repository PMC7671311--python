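"""Weighted greedy set cover, term weights and gene-set similarity."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosynth.annotations import AnnotationTable
from gosynth.ontology import compute_ic
from gosynth.representatives import RepresentativeSet
from gosynth.synthesis import (
    gene_set_similarity,
    greedy_cover,
    greedy_set_cover,
    summarize,
    term_weight,
)

from conftest import A, A1, A2, B, B1, R, graph_from_edges, make_table


def _reps(coverage):
    return RepresentativeSet(
        reps=sorted(coverage),
        provenance={t: {0} for t in coverage},
        coverage={t: set(g) for t, g in coverage.items()},
    )


class TestTermWeight:
    @pytest.fixture
    def scoped_tables(self):
        # genome: 1000 annotated genes, term "t" annotates 10 of them;
        # gene set: 20 annotated genes, 5 of them under "t"
        g = graph_from_edges([("t", "R0", "is_a"), ("u", "R0", "is_a")])
        genome = {f"g{i}": {"t"} for i in range(10)}
        genome.update({f"x{i}": {"u"} for i in range(990)})
        gene_set = {f"g{i}": {"t"} for i in range(5)}
        gene_set.update({f"y{i}": {"u"} for i in range(15)})
        return (
            g,
            make_table(genome, scope="genome"),
            make_table(gene_set, scope="gene_set"),
        )

    def test_hand_value(self, scoped_tables):
        g, genome, gene_set = scoped_tables
        w = term_weight("t", gene_set, genome, g)
        assert w == pytest.approx(math.log(100) / math.log(4), abs=1e-9)
        assert w == pytest.approx(3.3219, abs=5e-4)

    def test_equal_fractions_weigh_one(self):
        g = graph_from_edges([("t", "R0", "is_a"), ("u", "R0", "is_a")])
        genome = make_table(
            {**{f"g{i}": {"t"} for i in range(5)},
             **{f"x{i}": {"u"} for i in range(15)}}, scope="genome")
        gene_set = make_table(
            {**{f"g{i}": {"t"} for i in range(5)},
             **{f"x{i}": {"u"} for i in range(15)}}, scope="gene_set")
        assert term_weight("t", gene_set, genome, g) == pytest.approx(1.0)

    def test_whole_set_coverage_capped(self, caplog):
        import logging
        g = graph_from_edges([("t", "R0", "is_a"), ("u", "R0", "is_a")])
        genome = make_table(
            {**{f"g{i}": {"t"} for i in range(20)},
             **{f"x{i}": {"u"} for i in range(80)}}, scope="genome")
        gene_set = make_table({f"g{i}": {"t"} for i in range(20)},
                              scope="gene_set")
        with caplog.at_level(logging.WARNING):
            w = term_weight("t", gene_set, genome, g)
        assert w == pytest.approx(-math.log(0.2) / 1e-6)
        assert "capped" in caplog.text

    def test_weight_counts_roll_up_descendants(self, toy_graph):
        # A annotates nothing directly, but its children do
        genome = make_table({"g1": {A1}, "g2": {A2}, "g3": {B1}}, scope="genome")
        gene_set = make_table({"g1": {A1}, "g3": {B1}}, scope="gene_set")
        w = term_weight(A, gene_set, genome, toy_graph)
        assert w == pytest.approx(-math.log(2 / 3) / -math.log(1 / 2))

    def test_unused_term_rejected(self, toy_graph):
        genome = make_table({"g1": {A1}}, scope="genome")
        gene_set = make_table({"g1": {A1}}, scope="gene_set")
        with pytest.raises(ValueError, match="no gene"):
            term_weight(B1, gene_set, genome, toy_graph)


def _unweighted_greedy_oracle(coverage):
    """Textbook greedy set cover: largest uncovered gain first."""
    covered, picked = set(), []
    remaining = dict(coverage)
    while True:
        best = max(
            sorted(remaining),
            key=lambda t: len(remaining[t] - covered),
            default=None,
        )
        if best is None or not (remaining[best] - covered):
            break
        picked.append(best)
        covered |= remaining.pop(best)
    return picked, covered


def _optimal_cover_size(coverage, universe):
    for r in range(1, len(coverage) + 1):
        for combo in combinations(sorted(coverage), r):
            if set().union(*(coverage[t] for t in combo)) == universe:
                return r
    return None


class TestGreedyCover:
    def test_hand_instance_full_coverage(self):
        coverage = {
            "T1": {"g1", "g2", "g3"}, "T2": {"g3", "g4"},
            "T3": {"g4", "g5"}, "T4": {"g5"},
        }
        w = {t: 1.0 for t in coverage}
        ic = {t: 1.0 for t in coverage}
        picked, covered = greedy_cover(coverage, w, ic)
        assert picked == ["T1", "T3"]
        assert covered == {"g1", "g2", "g3", "g4", "g5"}

    def test_single_covering_rep(self):
        coverage = {"T1": {"g1", "g2"}}
        picked, covered = greedy_cover(coverage, {"T1": 1.0}, {"T1": 1.0})
        assert picked == ["T1"] and covered == {"g1", "g2"}

    def test_heavy_weight_changes_order_not_coverage(self):
        coverage = {
            "T1": {"g1", "g2", "g3"}, "T2": {"g3", "g4"}, "T3": {"g4", "g5"},
        }
        w = {"T1": 1.0, "T2": 100.0, "T3": 1.0}
        ic = {t: 1.0 for t in coverage}
        picked, covered = greedy_cover(coverage, w, ic)
        assert picked[0] == "T2"
        assert covered == {"g1", "g2", "g3", "g4", "g5"}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equal_weights_reduce_to_textbook_greedy(self, seed):
        rng = np.random.default_rng(seed)
        n_sets, n_genes = int(rng.integers(2, 9)), int(rng.integers(3, 12))
        coverage = {
            f"T{i}": set(f"g{j}" for j in rng.choice(
                n_genes, size=int(rng.integers(1, n_genes + 1)), replace=False))
            for i in range(n_sets)
        }
        w = {t: 1.0 for t in coverage}
        ic = {t: 0.0 for t in coverage}
        picked, covered = greedy_cover(coverage, w, ic)
        o_picked, o_covered = _unweighted_greedy_oracle(coverage)
        assert covered == o_covered
        assert len(picked) == len(o_picked)

    @pytest.mark.parametrize("seed", range(50))
    def test_within_log_bound_of_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n_sets, n_genes = int(rng.integers(3, 10)), int(rng.integers(4, 13))
        coverage = {
            f"T{i}": set(f"g{j}" for j in rng.choice(
                n_genes, size=int(rng.integers(1, n_genes + 1)), replace=False))
            for i in range(n_sets)
        }
        universe = set().union(*coverage.values())
        w = {t: 1.0 for t in coverage}
        ic = {t: 0.0 for t in coverage}
        picked, covered = greedy_cover(coverage, w, ic)
        assert covered == universe
        m = max(len(s) for s in coverage.values())
        opt = _optimal_cover_size(coverage, universe)
        assert len(picked) <= (1 + math.log(m)) * opt + 1e-9

    def test_every_pick_strictly_grows_coverage(self):
        rng = np.random.default_rng(7)
        coverage = {
            f"T{i}": set(f"g{j}" for j in rng.choice(10, size=4, replace=False))
            for i in range(6)
        }
        w = {t: float(rng.uniform(0.5, 3)) for t in coverage}
        ic = {t: float(rng.uniform(0, 5)) for t in coverage}
        picked, _ = greedy_cover(coverage, w, ic)
        seen: set = set()
        for t in picked:
            assert coverage[t] - seen
            seen |= coverage[t]

    def test_empty_reps_empty_result(self, toy_graph, toy_stats):
        genome = make_table({"g1": {A1}}, scope="genome")
        gene_set = make_table({"g1": {A1}}, scope="gene_set")
        result = greedy_set_cover(_reps({}), gene_set, genome, toy_graph, toy_stats)
        assert result.synthetic == [] and result.covered_genes == set()


class TestGeneSetSimilarity:
    def test_identical_annotations_score_one(self, toy_graph, toy_stats):
        table = make_table({"g1": {A1, B1}, "g2": {A1, B1}, "g3": {A1, B1}})
        assert gene_set_similarity(table, toy_graph, toy_stats) == pytest.approx(1.0)

    def test_disjoint_branches_score_zero(self, toy_graph, toy_stats):
        table = make_table({"g1": {A1}, "g2": {B1}})
        assert gene_set_similarity(table, toy_graph, toy_stats) == pytest.approx(0.0)

    def test_hand_value_shared_parent(self, toy_graph, toy_stats):
        table = make_table({"g1": {A1}, "g2": {A2}})
        v = gene_set_similarity(table, toy_graph, toy_stats)
        expected = math.log(5) / (math.log(5) + math.log(50) + math.log(50))
        assert v == pytest.approx(expected, abs=1e-9)
        assert v == pytest.approx(0.1706, abs=5e-4)

    def test_single_gene_undefined(self, toy_graph, toy_stats):
        table = make_table({"g1": {A1}})
        assert math.isnan(gene_set_similarity(table, toy_graph, toy_stats))

    def test_gene_order_invariance(self, toy_graph, toy_stats):
        t1 = make_table({"g1": {A1}, "g2": {A2}, "g3": {B1}})
        t2 = make_table({"g3": {B1}, "g1": {A1}, "g2": {A2}})
        assert gene_set_similarity(t1, toy_graph, toy_stats) == \
            gene_set_similarity(t2, toy_graph, toy_stats)

    def test_bounds(self, toy_graph, toy_stats):
        for genes in ({"g1": {A1}, "g2": {A1, A2}},
                      {"g1": {A}, "g2": {A2}, "g3": {B}}):
            v = gene_set_similarity(make_table(genes), toy_graph, toy_stats)
            assert 0.0 <= v <= 1.0


class TestSummarize:
    def test_percentages(self, toy_graph, toy_stats):
        genome = make_table(
            {f"g{i}": {A1} for i in range(81)}, scope="genome")
        reps = _reps({A1: {f"g{i}" for i in range(80)}})
        gene_set = make_table({f"g{i}": {A1} for i in range(81)},
                              scope="gene_set")
        result = greedy_set_cover(reps, gene_set, genome, toy_graph, toy_stats)
        summary = summarize(result, gene_set, raw_gene_count=81)
        assert summary["covered_gene_pct"] == pytest.approx(100 * 80 / 81)
        assert summary["covered_gene_pct"] == pytest.approx(98.77, abs=5e-3)
        assert summary["annotated_gene_pct"] == pytest.approx(100.0)

    def test_zero_synthetic_terms_well_formed(self, toy_graph, toy_stats):
        genome = make_table({"g1": {A1}}, scope="genome")
        gene_set = make_table({"g1": {A1}}, scope="gene_set")
        result = greedy_set_cover(_reps({}), gene_set, genome, toy_graph, toy_stats)
        summary = summarize(result, gene_set, raw_gene_count=5)
        assert summary["covered_gene_pct"] == 0.0
        assert summary["n_synthetic_terms"] == 0
        assert summary["per_term"] == []

    def test_per_term_sorted_by_pick_order(self, toy_graph, toy_stats):
        genome = make_table({"g1": {A1}, "g2": {A2}, "g3": {B1}}, scope="genome")
        gene_set = make_table({"g1": {A1}, "g2": {A2}, "g3": {B1}},
                              scope="gene_set")
        reps = _reps({A1: {"g1"}, A2: {"g2"}, B1: {"g3"}})
        result = greedy_set_cover(reps, gene_set, genome, toy_graph, toy_stats)
        summary = summarize(result, gene_set, raw_gene_count=3)
        orders = [row["pick_order"] for row in summary["per_term"]
                  if row["pick_order"] is not None]
        assert orders == sorted(orders)
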
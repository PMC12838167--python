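"""Candidate filtering, clique enumeration, and cocktail optimization."""

import itertools
import math

import numpy as np
import pytest

from phagecocktail import datasets
from phagecocktail.design import (
    DesignCriteria,
    complementarity_cliques,
    evaluate,
    filter_candidates,
    optimize,
)
from phagecocktail.errors import PhageCocktailError
from phagecocktail.hostrange import PairComplementarity, binarize, coverage
from phagecocktail.hostrange import CoverageReport
from phagecocktail.panel import PhageRecord, SusceptibilityMatrix


def _records(matrix, genus_of=None, verdict_of=None, class_of=None):
    out = []
    for i, p in enumerate(matrix.phages):
        out.append(
            PhageRecord(
                phage_id=p,
                genus=(genus_of or {}).get(p, f"genus{i % 3}"),
                genome_size=60000,
                lifestyle_verdict=(verdict_of or {}).get(p, "lytic"),
                receptor_class=(class_of or {}).get(p, 1 + i % 5),
            )
        )
    return out


class TestFilterCandidates:
    def test_temperate_phage_always_excluded(self, reconstructed, catalog):
        matrix, _ = reconstructed
        res = filter_candidates(catalog, matrix, DesignCriteria(require_lytic=True))
        assert "EPa33" in res.exclusions
        assert len(res.eligible) == 24

    def test_30_percent_floor_excludes_narrow_phages(self, reconstructed, catalog):
        matrix, _ = reconstructed
        res = filter_candidates(
            catalog, matrix,
            DesignCriteria(require_lytic=True, min_single_host_range=30.0),
        )
        narrow = {"EPa5", "EPa25", "EPa38", "EPa43"}
        assert narrow <= set(res.exclusions)
        assert set(res.eligible) & narrow == set()
        # EPa17 at 30.8% sits just above the floor and stays in
        assert "EPa17" in res.eligible

    def test_impossible_floor_names_binding_constraint(self, small_matrix):
        with pytest.raises(PhageCocktailError, match="min_single_host_range"):
            filter_candidates(
                _records(small_matrix), small_matrix,
                DesignCriteria(min_single_host_range=100.0),
            )


class TestCliques:
    def _pair(self, a, b, comp):
        dummy = CoverageReport(frozenset({a}), 1 + comp, 10)
        base = CoverageReport(frozenset({a}), 1, 10)
        return PairComplementarity(a, b, base, base, dummy)

    def test_edgeless_graph_only_singletons(self):
        table = [self._pair("A", "B", False), self._pair("B", "C", False)]
        assert complementarity_cliques(table, size=1) == [("A",), ("B",), ("C",)]
        assert complementarity_cliques(table, size=2) == []

    def test_seven_clique_reported(self, reconstructed):
        matrix, _ = reconstructed
        from phagecocktail.hostrange import pairwise_union_table

        seven = list(datasets.MIX7)
        table = pairwise_union_table(matrix, seven)
        assert tuple(sorted(seven)) in complementarity_cliques(table)

    def test_matches_bruteforce_triangles_on_random_graphs(self, rng):
        nodes = [f"N{i}" for i in range(10)]
        for trial in range(5):
            edges = {
                frozenset(e): bool(rng.random() < 0.5)
                for e in itertools.combinations(nodes, 2)
            }
            table = [
                self._pair(a, b, edges[frozenset((a, b))])
                for a, b in itertools.combinations(nodes, 2)
            ]
            expected = sorted(
                tuple(sorted(t))
                for t in itertools.combinations(nodes, 3)
                if all(edges[frozenset(p)] for p in itertools.combinations(t, 2))
            )
            assert complementarity_cliques(table, size=3) == expected


class TestEvaluate:
    def test_single_phage_cocktail_equals_host_range(self, small_matrix):
        records = {r.phage_id: r for r in _records(small_matrix)}
        ev = evaluate(["P1"], small_matrix, records)
        assert ev.coverage.covered_count == coverage(small_matrix, ["P1"]).covered_count

    def test_pam1_covers_55_8(self, reconstructed, catalog_map):
        matrix, _ = reconstructed
        ev = evaluate(datasets.PAM1, matrix, catalog_map)
        assert ev.coverage.covered_count == 87
        assert ev.coverage.percent == 55.8

    def test_pam2_diversity_and_coverage(self, reconstructed, catalog_map):
        matrix, _ = reconstructed
        singles, _ = datasets.resistance_table()
        ev = evaluate(datasets.PAM2, matrix, catalog_map, resistance=singles)
        assert ev.coverage.percent == 76.3
        assert ev.distinct_receptor_classes == 3
        assert ev.distinct_genera == 3
        assert ev.worst_resistance == pytest.approx(9.39e-6)

    def test_unresolved_member_raises(self, small_matrix):
        with pytest.raises(Exception, match="P99"):
            evaluate(["P99"], small_matrix, {})


class TestOptimize:
    def test_k1_exhaustive_finds_broadest_single(self, reconstructed, catalog_map):
        matrix, _ = reconstructed
        crit = DesignCriteria(cocktail_size=1, min_receptor_classes=0,
                              min_genera=0, require_lytic=True)
        lytic = [p for p in matrix.phages if p != "EPa33"]
        res = optimize(matrix, catalog_map, crit, candidates=lytic)
        assert res.best.members == ("EPa15",)
        assert res.best.coverage.percent == 54.5

    def test_exhaustive_at_least_greedy(self, rng):
        for trial in range(3):
            binary = rng.random((8, 30)) < 0.35
            m = SusceptibilityMatrix.from_binary(
                [f"P{i}" for i in range(8)], [f"S{j}" for j in range(30)], binary
            )
            recs = {r.phage_id: r for r in _records(m)}
            crit = DesignCriteria(cocktail_size=3, min_receptor_classes=0,
                                  min_genera=0)
            ex = optimize(m, recs, crit, mode="exhaustive")
            gr = optimize(m, recs, crit, mode="greedy")
            assert ex.best.coverage.covered_count >= gr.best.coverage.covered_count

    def test_greedy_within_1_minus_1_over_e(self, rng):
        # classical approximation bound for accretive maximum coverage
        bound = 1 - 1 / math.e
        for trial in range(4):
            binary = rng.random((12, 40)) < 0.3
            m = SusceptibilityMatrix.from_binary(
                [f"P{i:02d}" for i in range(12)], [f"S{j}" for j in range(40)], binary
            )
            recs = {r.phage_id: r for r in _records(m)}
            for k in (3, 4):
                crit = DesignCriteria(cocktail_size=k, min_receptor_classes=0,
                                      min_genera=0)
                ex = optimize(m, recs, crit, mode="exhaustive")
                gr = optimize(m, recs, crit, mode="greedy")
                assert (
                    gr.best.coverage.covered_count
                    >= bound * ex.best.coverage.covered_count
                )

    def test_adding_constraints_never_improves_best_coverage(self, reconstructed,
                                                             catalog_map):
        matrix, _ = reconstructed
        lytic = [p for p in matrix.phages if p != "EPa33"]
        loose = DesignCriteria(cocktail_size=3, min_receptor_classes=0, min_genera=0)
        tight = DesignCriteria(cocktail_size=3, min_receptor_classes=3, min_genera=3)
        best_loose = optimize(matrix, catalog_map, loose, candidates=lytic).best
        best_tight = optimize(matrix, catalog_map, tight, candidates=lytic).best
        assert best_tight.coverage.covered_count <= best_loose.coverage.covered_count

    def test_ranking_deterministic(self, small_matrix):
        recs = {r.phage_id: r for r in _records(small_matrix)}
        crit = DesignCriteria(cocktail_size=2, min_receptor_classes=0, min_genera=0)
        a = optimize(small_matrix, recs, crit)
        b = optimize(small_matrix, recs, crit)
        assert [e.members for e in a.ranked] == [e.members for e in b.ranked]

    def test_budget_refusal(self, reconstructed, catalog_map):
        matrix, _ = reconstructed
        crit = DesignCriteria(cocktail_size=5, min_receptor_classes=0, min_genera=0)
        with pytest.raises(PhageCocktailError, match="budget"):
            optimize(matrix, catalog_map, crit, budget=10)

    def test_no_feasible_subset_yields_failure_census(self, small_matrix):
        recs = {
            r.phage_id: r
            for r in _records(small_matrix, class_of={p: 1 for p in small_matrix.phages})
        }
        crit = DesignCriteria(cocktail_size=2, min_receptor_classes=2, min_genera=0)
        res = optimize(small_matrix, recs, crit)
        assert res.ranked == []
        assert res.failure_census.get("receptor_diversity", 0) > 0
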
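"""Synthetic-data generators and the marginal-consistent reconstructor."""

import itertools

import numpy as np
import pytest

from phagecocktail.errors import InfeasibleSpecError, PhageCocktailError
from phagecocktail.hostrange import binarize, coverage, pairwise_union_table, percent
from phagecocktail.simulate import (
    CLASS_REQUIREMENTS,
    MarginalSpec,
    PanelConfig,
    generate_matrix,
    generate_panel,
    percent_to_count,
    reconstruct_matrix,
    simulate_plating,
)


class TestGeneratePanel:
    def test_deterministic_given_seed(self):
        cfg = PanelConfig(n_strains=40, st_count=20, seed=7)
        a_recs, a_geno = generate_panel(cfg)
        b_recs, b_geno = generate_panel(cfg)
        assert a_recs == b_recs and a_geno == b_geno

    def test_all_sts_unique_when_st_count_equals_n(self):
        recs, _ = generate_panel(PanelConfig(n_strains=30, st_count=30, seed=1))
        assert len({r.sequence_type for r in recs}) == 30

    def test_panel_scale_st_richness(self):
        recs, _ = generate_panel(PanelConfig(n_strains=156, st_count=106, seed=1))
        assert len(recs) == 156
        assert len({r.sequence_type for r in recs}) == 106

    def test_genotype_hierarchy_b_band_requires_core(self):
        _, geno = generate_panel(PanelConfig(n_strains=200, seed=3))
        for feats in geno.values():
            if "B_band" in feats or "A_band" in feats:
                assert "core" in feats
            if "long_B" in feats or "very_long_B" in feats:
                assert "B_band" in feats

    def test_bad_config_rejected(self):
        with pytest.raises(PhageCocktailError):
            PanelConfig(n_strains=0)
        with pytest.raises(PhageCocktailError):
            PanelConfig(immunity_prob=1.5)


class TestGenerateMatrix:
    def test_strain_without_t4p_resistant_to_everything(self):
        geno = {"S1": frozenset(), "S2": frozenset(CLASS_REQUIREMENTS[4] | {"core"})}
        m = generate_matrix(geno, {"P1": 1, "P2": 3}, immunity_prob=0.0, seed=0)
        b = binarize(m)
        assert not b[:, 0].any()
        assert b[:, 1].all()

    def test_immunity_one_all_resistant(self):
        _, geno = generate_panel(PanelConfig(n_strains=30, st_count=15, seed=2))
        m = generate_matrix(geno, {"P1": 2}, immunity_prob=1.0, seed=0)
        assert not binarize(m).any()

    def test_unknown_class_rejected(self):
        with pytest.raises(PhageCocktailError):
            generate_matrix({"S1": frozenset()}, {"P1": 9}, 0.0, seed=0)

    def test_mean_single_coverage_near_35_percent(self):
        # defaults are tuned to a realistic ~35% mean host range
        coverages = []
        for seed in range(20):
            cfg = PanelConfig(n_strains=100, st_count=60, seed=seed)
            _, geno = generate_panel(cfg)
            classes = {f"P{i}": 1 + i % 5 for i in range(10)}
            m = generate_matrix(geno, classes, cfg.immunity_prob, seed=seed + 1000)
            b = binarize(m)
            coverages.extend(b.mean(axis=1) * 100)
        assert abs(np.mean(coverages) - 35.0) <= 5.0

    def test_nested_requirements_give_nested_ranges_non_complementary(self):
        _, geno = generate_panel(PanelConfig(n_strains=80, st_count=40, seed=5))
        # class 4 requires a superset of class 3's features
        m = generate_matrix(geno, {"P3": 3, "P4": 4}, immunity_prob=0.0, seed=0)
        b = binarize(m)
        assert (b[1] <= b[0]).all()
        (rec,) = pairwise_union_table(m, ["P3", "P4"])
        assert not rec.complementary


class TestPercentToCount:
    @pytest.mark.parametrize(
        "p,k", [(51.3, 80), (30.8, 48), (54.5, 85), (7.7, 12),
                (85.3, 133), (76.3, 119), (55.8, 87)]
    )
    def test_inversion_round_trips_printed_values(self, p, k):
        assert percent_to_count(p, 156) == k
        assert percent(k, 156) == p


class TestReconstruction:
    def test_toy_spec_achievable_and_verified_exhaustively(self):
        # 3 phages on 6 strains, singles 2 each, pair unions 4: solutions
        # exist (brute force over all 3x6 binary matrices), and the search
        # finds one
        spec = MarginalSpec(
            panel_size=6,
            single_coverages={"A": percent(2, 6), "B": percent(2, 6),
                              "C": percent(2, 6)},
            pair_unions={("A", "B"): percent(4, 6), ("A", "C"): percent(4, 6),
                         ("B", "C"): percent(4, 6)},
        )
        feasible = False
        cols = list(itertools.combinations(range(6), 2))
        for sa, sb, sc in itertools.product(cols, repeat=3):
            ok = all(
                len(set(x) | set(y)) == 4
                for x, y in itertools.combinations((sa, sb, sc), 2)
            )
            if ok:
                feasible = True
                break
        assert feasible
        m, rep = reconstruct_matrix(spec, seed=0, max_iters=20_000)
        assert rep.satisfied
        b = binarize(m)
        assert [int(r.sum()) for r in b] == [2, 2, 2]

    def test_union_below_single_is_infeasible_before_search(self):
        spec = MarginalSpec(
            panel_size=10,
            single_coverages={"A": 50.0, "B": 20.0},
            pair_unions={("A", "B"): 40.0},
        )
        with pytest.raises(InfeasibleSpecError, match="outside"):
            reconstruct_matrix(spec, seed=0)

    def test_pair_phage_without_single_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            MarginalSpec(panel_size=10, single_coverages={"A": 50.0},
                         pair_unions={("A", "B"): 60.0})

    def test_published_spec_single_coverages_exact(self, reconstructed,
                                                   published_spec):
        matrix, report = reconstructed
        b = binarize(matrix)
        for i, pid in enumerate(matrix.phages):
            k = percent_to_count(published_spec.single_coverages[pid], 156)
            assert int(b[i].sum()) == k

    def test_published_spec_constraints_within_tolerance(self, reconstructed):
        _, report = reconstructed
        assert report.satisfied
        assert report.max_deviation_pp <= 0.2
        # deviation report covers every pair and set constraint
        assert len(report.rows) == 21 + 5

    def test_reconstruction_deterministic_given_seed(self, published_spec):
        a, _ = reconstruct_matrix(published_spec, seed=9, max_iters=60_000,
                                  restarts=1)
        b, _ = reconstruct_matrix(published_spec, seed=9, max_iters=60_000,
                                  restarts=1)
        assert a == b


class TestSimulatePlating:
    def test_zero_frequency_always_zero_colonies(self):
        for seed in range(5):
            assay = simulate_plating(0.0, 1e8, seed=seed)
            assert assay.challenge_colonies == 0

    def test_poisson_mean_recovered(self):
        counts = [
            simulate_plating(1e-6, 1e8, seed=s).challenge_colonies
            for s in range(1000)
        ]
        assert abs(np.mean(counts) - 100) / 100 < 0.1

    def test_fixed_seed_reproducible(self):
        a = simulate_plating(1e-6, 1e8, seed=42)
        b = simulate_plating(1e-6, 1e8, seed=42)
        assert a == b

    def test_invalid_parameters(self):
        with pytest.raises(PhageCocktailError):
            simulate_plating(1.5, 1e8, seed=0)
        with pytest.raises(PhageCocktailError):
            simulate_plating(1e-6, 0, seed=0)
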
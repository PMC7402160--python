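"""Synthetic-data generator: determinism, conservation laws and convergence
of the simulated populations to their closed-form distributions."""

import numpy as np
import pytest
from scipy import stats

import combisort as cs
from combisort import ElementClass


class TestDrawEffects:
    def test_deterministic_for_fixed_seed(self, catalog):
        a = cs.draw_effects(catalog, seed=1)
        b = cs.draw_effects(catalog, seed=1)
        for cls in a.effects:
            np.testing.assert_array_equal(a.effects[cls], b.effects[cls])
            np.testing.assert_array_equal(a.sigma_offsets[cls], b.sigma_offsets[cls])

    def test_zero_utr_sd_collapses_utr_variation(self, catalog):
        cfg = cs.EffectConfig(utr5_sd=0.0, utr3_sd=0.0, sigma_range=(0.5, 0.5))
        truth = cs.draw_effects(catalog, cfg, seed=2)
        # all constructs sharing (enhancer, promoter) have identical mu
        mus = truth.mu([0, 0, 0], [0, 0, 0], [0, 1, 2], [3, 4, 5])
        assert np.ptp(mus) == pytest.approx(0.0, abs=1e-9)

    def test_class_effect_spread_ranking(self, catalog):
        cfg = cs.EffectConfig(
            enhancer_sd=1.5, promoter_sd=0.8, utr5_sd=0.1, utr3_sd=0.1,
            inactive_enhancer_fraction=0.0,
        )
        pooled = {cls: [] for cls in cs.parts.VARIABLE_CLASSES}
        for seed in range(1000):
            truth = cs.draw_effects(catalog, cfg, seed=seed)
            for cls in pooled:
                pooled[cls].append(truth.effects[cls])
        var = {cls: np.var(np.concatenate(v)) for cls, v in pooled.items()}
        assert var[ElementClass.ENHANCER] > var[ElementClass.PROMOTER]
        assert var[ElementClass.PROMOTER] > 5 * var[ElementClass.UTR5]
        assert var[ElementClass.UTR5] == pytest.approx(var[ElementClass.UTR3], rel=0.25)

    def test_median_construct_inside_gates(self, catalog, gates):
        truth = cs.draw_effects(catalog, seed=3)
        sizes = truth.class_sizes
        rng = np.random.default_rng(0)
        mus = truth.mu(
            rng.integers(0, sizes[ElementClass.ENHANCER], 2000),
            rng.integers(0, sizes[ElementClass.PROMOTER], 2000),
            rng.integers(0, sizes[ElementClass.UTR5], 2000),
            rng.integers(0, sizes[ElementClass.UTR3], 2000),
        )
        a1, _, a3 = gates.boundaries
        assert a1 < np.median(mus) < a3

    def test_invalid_config_rejected(self, catalog):
        with pytest.raises(ValueError):
            cs.draw_effects(catalog, cs.EffectConfig(sigma_range=(0.0, 0.5)))
        with pytest.raises(ValueError):
            cs.draw_effects(catalog, cs.EffectConfig(enhancer_sd=-1.0))


class TestLibrary:
    def test_single_clone(self, catalog):
        truth = cs.draw_effects(catalog, seed=4)
        lib = cs.simulate_library(truth, 1, seed=0)
        assert lib.n_clones == lib.n_distinct == 1

    def test_singleton_space_yields_copies(self, toy_parts):
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), seed=0)
        lib = cs.simulate_library(truth, 100, seed=0)
        assert lib.n_distinct == 1
        assert lib.counts[0] == 100

    def test_distinct_fraction_matches_coverage_formula(self, small_catalog):
        truth = cs.draw_effects(small_catalog, seed=5)
        space = cs.enumerate_space(small_catalog, usable_only=True)  # 5^4 = 625
        n = 800
        lib = cs.simulate_library(truth, n, seed=6)
        expected = cs.expected_coverage(n, space)
        # sd of the covered fraction is ~sqrt(N p q)/N
        se = np.sqrt(space * expected * (1 - expected)) / space
        assert abs(lib.n_distinct / space - expected) < 4 * se


class TestSort:
    def test_cell_conservation(self, pipeline):
        pop, lib = pipeline["population"], pipeline["library"]
        assert pop.total_cells == lib.n_clones * 50
        np.testing.assert_array_equal(pop.cells_per_bin, pop.cell_counts.sum(axis=0))

    def test_extreme_construct_all_in_none(self, toy_parts, gates):
        cfg = cs.EffectConfig(baseline_mu=1e-3, sigma_range=(0.1, 0.1))
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        lib = cs.simulate_library(truth, 10, seed=0)
        pop = cs.simulate_sort(truth, lib, 1000, gates=gates, seed=0)
        assert pop.cells_per_bin[0] == pop.total_cells

    def test_point_mass_in_low_bin(self, toy_parts, gates):
        a1, a2, _ = gates.boundaries
        cfg = cs.EffectConfig(
            enhancer_sd=0, promoter_sd=0, utr5_sd=0, utr3_sd=0,
            inactive_enhancer_fraction=0.0,
            baseline_mu=float(np.sqrt(a1 * a2)), sigma_range=(1e-6, 1e-6),
        )
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        lib = cs.simulate_library(truth, 5, seed=0)
        pop = cs.simulate_sort(truth, lib, 2000, gates=gates, seed=0)
        assert pop.cells_per_bin[1] == pop.total_cells

    def test_median_at_gate_splits_evenly(self, toy_parts):
        gates = cs.SortGates((100.0, 1_000.0, 10_000.0))
        cfg = cs.EffectConfig(
            enhancer_sd=0, promoter_sd=0, utr5_sd=0, utr3_sd=0,
            inactive_enhancer_fraction=0.0,
            baseline_mu=1_000.0, sigma_range=(0.5, 0.5),
        )
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        lib = cs.simulate_library(truth, 1, seed=0)
        n = 200_000
        pop = cs.simulate_sort(truth, lib, n, gates=gates, seed=1)
        below = pop.cells_per_bin[:2].sum() / n
        assert below == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / n))

    def test_bin_fractions_converge_to_closed_form(self, catalog, gates):
        truth = cs.draw_effects(catalog, seed=7)
        lib = cs.simulate_library(truth, 20, seed=8)
        n = 50_000
        pop = cs.simulate_sort(truth, lib, n, gates=gates, seed=9)
        mu = truth.mu(lib.e_idx, lib.p_idx, lib.u5_idx, lib.u3_idx)
        sigma = truth.sigma(lib.e_idx, lib.p_idx, lib.u5_idx, lib.u3_idx)
        expected = gates.bin_probabilities(mu, sigma)
        observed = pop.cell_counts / pop.cell_counts.sum(axis=1, keepdims=True)
        tol = 4 * np.sqrt(expected * (1 - expected) / (lib.counts[:, None] * n)) + 1e-9
        assert np.all(np.abs(observed - expected) <= tol)


class TestReads:
    def test_no_dropout_means_complete_reads(self, catalog, gates):
        truth = cs.draw_effects(catalog, seed=10)
        lib = cs.simulate_library(truth, 500, seed=11)
        pop = cs.simulate_sort(truth, lib, 20, gates=gates, seed=12)
        reads = cs.simulate_reads(pop, 5_000, dropout_rate=0.0, seed=13)
        assert reads.records[["enhancer", "promoter", "utr5", "utr3"]].notna().all().all()

    def test_read_conservation_and_totals(self, pipeline):
        reads = pipeline["reads"]
        per_bin = reads.records.groupby("bin").size()
        for label, r in reads.reads_per_bin.items():
            assert per_bin.get(label, 0) == r
        assert reads.n_reads == reads.reads_per_bin.sum() == 300_000

    def test_single_construct_bin_maps_to_it(self, toy_parts, gates):
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), seed=0)
        lib = cs.simulate_library(truth, 10, seed=0)
        pop = cs.simulate_sort(truth, lib, 100, gates=gates, seed=0)
        reads = cs.simulate_reads(pop, 1_000, dropout_rate=0.0, seed=0)
        assert (reads.records["enhancer"] == "TDH3_enhancer").all()

    def test_empty_bin_warns_and_yields_zero(self, toy_parts, gates):
        cfg = cs.EffectConfig(baseline_mu=1e-3, sigma_range=(0.1, 0.1))
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        lib = cs.simulate_library(truth, 5, seed=0)
        pop = cs.simulate_sort(truth, lib, 100, gates=gates, seed=0)
        with pytest.warns(UserWarning):
            reads = cs.simulate_reads(pop, [10, 10, 10, 10], dropout_rate=0.0, seed=0)
        assert reads.reads_per_bin["high"] == 0

    def test_disproportionate_read_shares(self, pipeline):
        # option reproducing the assay's uneven sequencing depth per bin
        pop = pipeline["population"]
        reads = cs.simulate_reads(
            pop, 10_000, dropout_rate=0.0, seed=5, read_shares=(0.61, 0.19, 0.05, 0.14)
        )
        target = np.array([0.61, 0.19, 0.05, 0.14])
        shares = reads.reads_per_bin / reads.reads_per_bin.sum()
        # the printed shares total 99%; the simulator renormalizes them
        np.testing.assert_allclose(shares.values, target / target.sum(), atol=1e-3)


class TestCytometry:
    def test_reproducible_and_near_degenerate(self, toy_parts):
        cfg = cs.EffectConfig(sigma_range=(1e-9, 1e-9), baseline_mu=500.0,
                              enhancer_sd=0, promoter_sd=0, utr5_sd=0, utr3_sd=0,
                              inactive_enhancer_fraction=0.0)
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        ids = ("TDH3_enhancer", "TDH3_promoter", "TDH3_utr5", "TDH3_utr3")
        a = cs.simulate_cytometry(truth, ids, 100, seed=1)
        b = cs.simulate_cytometry(truth, ids, 100, seed=1)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a, 500.0, rtol=1e-6)
        assert cs.fano(a).fano == pytest.approx(0.0, abs=1e-6)

    def test_lognormal_moment(self, toy_parts):
        cfg = cs.EffectConfig(sigma_range=(0.5, 0.5), baseline_mu=100.0,
                              enhancer_sd=0, promoter_sd=0, utr5_sd=0, utr3_sd=0,
                              inactive_enhancer_fraction=0.0)
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), cfg, seed=0)
        ids = ("TDH3_enhancer", "TDH3_promoter", "TDH3_utr5", "TDH3_utr3")
        sample = cs.simulate_cytometry(truth, ids, 100_000, seed=2)
        assert sample.mean() == pytest.approx(100.0 * np.exp(0.125), rel=0.02)

    def test_too_few_cells_rejected(self, toy_parts):
        truth = cs.draw_effects(cs.PartsCatalog(list(toy_parts)), seed=0)
        ids = ("TDH3_enhancer", "TDH3_promoter", "TDH3_utr5", "TDH3_utr3")
        with pytest.raises(ValueError):
            cs.simulate_cytometry(truth, ids, 1, seed=0)
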
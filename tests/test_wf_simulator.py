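"""Clone-based Wright-Fisher dynamics: drift, selection, bottlenecks, CCF."""

import numpy as np
import pytest
from scipy import stats

from tallevo.wf_simulator import (
    CCFComparison,
    ClonePopulation,
    SimConfig,
    bottleneck_random,
    bottleneck_resistant,
    compare_ccf,
    evolve,
    regrow,
    run_scenario,
)

SMALL = SimConfig(
    pop_size=100, mu=0.0, burn_in_generations=10, compact_interval=0,
    bottleneck_removed_range=(10, 10),
)


def _two_clones(n1=10, n2=90, site1=500, site2=600):
    # two neutral clones, one mutation each (passenger namespace)
    return ClonePopulation.from_clones([((site1,), n1, 1.0), ((site2,), n2, 1.0)])


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(pop_size=0)
        with pytest.raises(ValueError):
            SimConfig(mu=1.5)
        with pytest.raises(ValueError):
            SimConfig(bottleneck_removed_range=(10, 5))
        with pytest.raises(ValueError):
            SimConfig(fitness_rule="geometric")

    def test_fitness_rules(self):
        cfg = SimConfig(driver_fitness=0.1)
        assert cfg.clone_fitness(2) == pytest.approx(1.1**2)
        add = SimConfig(driver_fitness=0.1, fitness_rule="additive")
        assert add.clone_fitness(2) == pytest.approx(1.2)


class TestClonePopulation:
    def test_clone_materialization_roundtrip(self):
        pop = _two_clones()
        clones = sorted(pop.clones(), key=lambda c: c[1])
        assert clones[0][1] == 10 and clones[1][1] == 90
        assert pop.total_cells == 100

    def test_mutation_counts_follow_the_genealogy(self):
        # nested clones: child carries parent's mutation too
        pop = ClonePopulation.from_clones([((1,), 30, 1.0), ((1, 2), 20, 1.0)])
        rows, counts = pop.mutation_counts()
        by_site = dict(zip(pop.store.site[rows], counts))
        assert by_site[1] == 50 and by_site[2] == 20

    def test_compaction_preserves_frequencies(self):
        cfg = SimConfig(pop_size=500, mu=1e-7, compact_interval=0)
        pop = ClonePopulation.founding(cfg.pop_size)
        evolve(pop, 200, cfg, seed=3)
        rows, before = pop.mutation_frequencies()
        sites_before = sorted(zip(pop.store.site[rows], before))
        pop.compact()
        rows, after = pop.mutation_frequencies()
        sites_after = sorted(zip(pop.store.site[rows], after))
        assert np.allclose([f for _, f in sites_before], [f for _, f in sites_after])
        assert [s for s, _ in sites_before] == [s for s, _ in sites_after]


class TestEvolve:
    def test_population_size_is_conserved(self):
        cfg = SimConfig(pop_size=1000, mu=1e-6, compact_interval=0)
        pop = ClonePopulation.founding(cfg.pop_size)
        for _ in range(5):
            evolve(pop, 10, cfg, seed=_)
            assert pop.total_cells == cfg.pop_size

    def test_no_mutation_means_drift_only(self):
        pop = _two_clones()
        n_rows = pop.store.n_rows
        evolve(pop, 20, SMALL, seed=2)
        assert pop.store.n_rows == n_rows  # mutation set unchanged
        assert pop.total_cells == 100

    def test_neutral_fixation_probability_equals_initial_frequency(self):
        """P(fix) of a neutral mutation equals its starting frequency."""
        p0, n_rep = 0.1, 1500
        fixed = 0
        for rep in range(n_rep):
            pop = _two_clones(n1=10, n2=90)
            rng = np.random.default_rng(1000 + rep)
            while pop.n_clones > 1:
                evolve(pop, 10, SMALL, rng)
            # which mutation survived?
            rows, counts = pop.mutation_counts()
            if pop.store.site[rows[0]] == 500:
                fixed += 1
        se = np.sqrt(p0 * (1 - p0) / n_rep)
        assert abs(fixed / n_rep - p0) < 3 * se

    def test_heterozygosity_decays_at_one_over_n(self):
        n, reps = 100, 3000
        rng = np.random.default_rng(5)
        h = []
        for _ in range(reps):
            pop = _two_clones(n1=50, n2=50)
            evolve(pop, 1, SMALL, rng)
            counts = dict(zip(pop.store.site[pop.clone_rows], pop.clone_counts))
            p = counts.get(500, 0) / n
            h.append(2 * p * (1 - p))
        expected = 0.5 * (1 - 1 / n)
        assert np.mean(h) == pytest.approx(expected, rel=0.02)

    def test_more_fit_drivers_fix_more_often(self):
        counts = {}
        for s in (0.01, 0.1):
            cfg = SimConfig(pop_size=3000, mu=2e-7, driver_fitness=s,
                            burn_in_generations=400, compact_interval=100)
            fixed = []
            for seed in range(4):
                pop = ClonePopulation.founding(cfg.pop_size)
                evolve(pop, cfg.burn_in_generations, cfg, seed=seed)
                pop.compact()
                fixed.append(pop.fixed_counts(cfg)[0])
            counts[s] = np.mean(fixed)
        assert counts[0.1] >= counts[0.01]

    def test_empty_population_rejected(self):
        pop = ClonePopulation.founding(10)
        pop.clone_counts = np.array([0])
        with pytest.raises(ValueError):
            evolve(pop, 1, SMALL, seed=0)


class TestBottlenecks:
    def test_removing_nothing_is_identity(self):
        cfg = SimConfig(pop_size=100, bottleneck_removed_range=(0, 0))
        pop = _two_clones()
        bottleneck_random(pop, cfg, seed=1)
        assert pop.total_cells == 100 and pop.n_clones == 2

    def test_single_survivor_matches_hypergeometric_enumeration(self):
        # 50 cells, remove 49: survivor carries mutation 500 w.p. 30/50
        cfg = SimConfig(pop_size=50, bottleneck_removed_range=(49, 49))
        hits, reps = 0, 2000
        for rep in range(reps):
            pop = _two_clones(n1=30, n2=20)
            bottleneck_random(pop, cfg, seed=rep)
            assert pop.total_cells == 1
            if pop.store.site[pop.clone_rows[0]] == 500:
                hits += 1
        p = stats.hypergeom(50, 30, 1).pmf(1)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3 * se

    def test_survivor_frequencies_are_unbiased(self):
        cfg = SimConfig(pop_size=100, bottleneck_removed_range=(60, 60))
        freqs = []
        for rep in range(1000):
            pop = _two_clones(n1=10, n2=90)
            bottleneck_random(pop, cfg, seed=rep)
            counts = dict(zip(pop.store.site[pop.clone_rows], pop.clone_counts))
            freqs.append(counts.get(500, 0) / pop.total_cells)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.1) < 3 * se

    def test_total_removal_is_an_error(self):
        cfg = SimConfig(pop_size=100, bottleneck_removed_range=(100, 100))
        with pytest.raises(ValueError):
            bottleneck_random(_two_clones(), cfg, seed=0)

    def test_resistant_marker_at_full_frequency_is_a_noop(self):
        pop = ClonePopulation.from_clones([((500,), 40, 1.0), ((500, 600), 60, 1.0)])
        bottleneck_resistant(pop, (0.9, 1.0), seed=1, cfg=SimConfig(pop_size=100))
        assert pop.total_cells == 100

    def test_resistant_marker_private_to_one_clone_selects_it(self):
        pop = ClonePopulation.from_clones([((500,), 95, 1.0), ((600,), 5, 1.0)])
        bottleneck_resistant(pop, (0.01, 0.1), seed=2, cfg=SimConfig(pop_size=100))
        assert pop.total_cells == 5
        rows, freqs = pop.mutation_frequencies()
        assert np.all(freqs == 1.0)  # every surviving mutation at CCF 1

    def test_no_qualifying_marker_is_an_error(self):
        pop = _two_clones(n1=50, n2=50)
        with pytest.raises(ValueError):
            bottleneck_resistant(pop, (1e-4, 1e-3), seed=0, cfg=SimConfig(pop_size=100))

    def test_marker_and_hitchhikers_fix_after_regrowth(self):
        cfg = SimConfig(pop_size=100, mu=0.0)
        pop = ClonePopulation.from_clones([((500,), 95, 1.0), ((600, 601), 5, 1.0)])
        bottleneck_resistant(pop, (0.01, 0.1), seed=3, cfg=cfg)
        marker = pop.resistant_marker_row
        regrow(pop, 100, 10, cfg, seed=4)
        rows, freqs = pop.mutation_frequencies()
        fixed_sites = set(pop.store.site[rows[freqs == 1.0]])
        assert {600, 601} <= fixed_sites
        assert pop.store.site[marker] in fixed_sites


class TestRegrow:
    def test_zero_generations_is_identity(self):
        pop = _two_clones()
        regrow(pop, 1000, 0, SMALL, seed=1)
        assert pop.total_cells == 100

    def test_growth_never_exceeds_target(self):
        cfg = SimConfig(pop_size=1000, mu=1e-6)
        pop = ClonePopulation.from_clones([((), 30, 1.0)])
        for _ in range(10):
            regrow(pop, 500, 1, cfg, seed=_)
            assert pop.total_cells <= 500

    def test_uncapped_growth_matches_branching_process_moments(self):
        """From one cell, offspring ~ Binomial(4, 1/2): mean 2^g, known var."""
        cfg = SimConfig(pop_size=10**9, mu=0.0)
        g, reps = 12, 400
        finals = []
        for rep in range(reps):
            pop = ClonePopulation.from_clones([((), 1, 1.0)])
            try:
                regrow(pop, 10**9, g, cfg, seed=rep)
                finals.append(pop.total_cells)
            except RuntimeError:
                finals.append(0)  # extinction of the branching process
        mean = 2.0**g
        var = 1.0 * 2 ** (g - 1) * (2**g - 1)  # sigma^2 m^(g-1)(m^g-1)/(m-1)
        se = np.sqrt(var / reps)
        assert abs(np.mean(finals) - mean) < 3 * se


class TestCCFComparison:
    def test_identical_populations_put_all_mass_at_high_ccf(self):
        cfg = SimConfig(pop_size=100)
        pop = ClonePopulation.from_clones([((500,), 100, 1.0)])
        comp = compare_ccf(pop, pop.copy(), cfg)
        assert comp.histogram[9] == pytest.approx(1.0)
        assert comp.n_fixed == 1

    def test_histogram_partitions_and_sums_to_one(self):
        cfg = SimConfig(pop_size=100)
        pop = ClonePopulation.from_clones(
            [((500,), 95, 1.0), ((600,), 5, 1.0)]
        )
        relapse = pop.copy()
        bottleneck_resistant(relapse, (0.01, 0.1), seed=1, cfg=cfg)
        regrow(relapse, 100, 5, cfg, seed=2)
        comp = compare_ccf(pop, relapse, cfg)
        assert comp.histogram.sum() == pytest.approx(1.0)
        assert comp.low_bin_mass > 0  # the CCF-0.05 marker became fixed
        assert len(comp.bin_edges) == 11

    def test_unrelated_genealogies_are_rejected(self):
        cfg = SimConfig(pop_size=100)
        a = ClonePopulation.from_clones([((500,), 100, 1.0)])
        b = ClonePopulation.from_clones([((500,), 100, 1.0)])
        with pytest.raises(ValueError):
            compare_ccf(a, b, cfg)

    def test_empty_fixed_set_is_flagged(self):
        cfg = SimConfig(pop_size=100)
        pop = ClonePopulation.from_clones([((500,), 50, 1.0), ((600,), 50, 1.0)])
        comp = compare_ccf(pop, pop.copy(), cfg)
        assert comp.empty and comp.n_fixed == 0
        assert comp.histogram.sum() == 0.0


class TestScenario:
    CFG = SimConfig(
        pop_size=5000, mu=5e-7, burn_in_generations=300, regrow_generations=20,
        bottleneck_removed_range=(500, 4500),
        resistant_marker_freq_range=(1e-3, 5e-2), compact_interval=100,
    )

    def test_fixed_seed_is_bit_reproducible(self):
        c1, s1 = run_scenario(self.CFG, "resistant", seed=9)
        c2, s2 = run_scenario(self.CFG, "resistant", seed=9)
        assert s1 == s2
        assert np.array_equal(c1.histogram, c2.histogram)

    def test_resistant_scenario_fixes_the_low_frequency_marker(self):
        comp, summary = run_scenario(self.CFG, "resistant", seed=11)
        assert comp.low_bin_mass > 0
        assert comp.histogram.sum() == pytest.approx(1.0)
        assert summary["marker_row"] is not None

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            run_scenario(self.CFG, "both", seed=0)
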
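import numpy as np
import pandas as pd
import pytest

from ecvmate.population import MARKER, QTL
from ecvmate.selection import CrossingPlan, PlanEntry
from ecvmate.simulate import (
    SCENARIO_PAIRS,
    SimConfig,
    advance_generation,
    build_genetic_map,
    derive_effects,
    generate_initial_population,
    genetic_values,
    run_scenario,
    scenario_config,
    simulate_phenotypes,
)


def small_config(**overrides):
    defaults = dict(
        k0=200,
        progeny_per_cross=20,
        pairs_per_generation=(8, 4, 3, 3),
        replications=2,
        seed=11,
        # tiny populations accumulate relatedness far faster than the
        # full-size benchmark; a loose cap keeps the block feasible
        epsilon=0.6,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def random_plan(pop, n_pairs, rng):
    picks = rng.choice(pop.n_individuals, size=(n_pairs, 2), replace=False)
    entries = [
        PlanEntry(int(a), int(b), pop.individual_id[a], pop.individual_id[b], (), float("nan"))
        for a, b in picks
    ]
    return CrossingPlan(entries=entries, method="random")


class TestGenomeLayout:
    def test_default_map_composition(self):
        gmap = build_genetic_map(SimConfig())
        assert gmap.n_loci == 300
        assert gmap.marker_indices.size == 100
        assert gmap.qtl_indices.size == 200
        assert len(np.unique(gmap.chromosome)) == 10

    def test_boundaries_and_within_chromosome_rates(self):
        gmap = build_genetic_map(SimConfig())
        boundary = np.flatnonzero(np.diff(gmap.chromosome) != 0)
        assert (gmap.r_adjacent[boundary] == 0.5).all()
        within = np.delete(gmap.r_adjacent, boundary)
        assert (within == 0.1).all()

    def test_interleaving_links_markers_to_qtl(self):
        gmap = build_genetic_map(SimConfig())
        # every marker has a QTL neighbour on the same chromosome
        classes = np.array([1 if c == QTL else 0 for c in gmap.locus_class])
        for m in gmap.marker_indices:
            neighbours = [i for i in (m - 1, m + 1) if 0 <= i < 300 and gmap.chromosome[i] == gmap.chromosome[m]]
            assert any(classes[i] for i in neighbours)


class TestInitialPopulation:
    def test_architecture_overlap_and_sizes(self, rng):
        pop, arch = generate_initial_population(SimConfig(k0=10), rng)
        assert [arch.n_loci(t) for t in arch.trait_ids] == [40, 10, 70]
        shared = set(arch.qtl_indices["trait1"]) & set(arch.qtl_indices["trait3"])
        assert len(shared) == 20
        # antagonistic loci carry opposite orientation for the two traits
        for locus in shared:
            i1 = list(arch.qtl_indices["trait1"]).index(locus)
            i3 = list(arch.qtl_indices["trait3"]).index(locus)
            assert arch.desirable_allele["trait1"][i1] != arch.desirable_allele["trait3"][i3]

    def test_allele_frequency_near_half(self, rng):
        pop, _ = generate_initial_population(SimConfig(k0=2000), rng)
        freqs = pop.alleles.mean(axis=(0, 2))
        se = np.sqrt(0.25 / (2 * 2000))
        assert abs(freqs.mean() - 0.5) < 0.01
        assert (np.abs(freqs - 0.5) < 5 * se).all()

    def test_trait_sizes_must_fit(self):
        with pytest.raises(ValueError):
            SimConfig(trait_sizes=(150, 50, 70), n_antagonistic=0)


class TestPhenotypes:
    def test_full_heritability_is_noiseless(self, rng):
        pop, arch = generate_initial_population(SimConfig(k0=50), rng)
        cfg = SimConfig(k0=50, heritability=1.0)
        eff = derive_effects(pop, arch, cfg)
        phen = simulate_phenotypes(pop, arch, eff, rng)
        np.testing.assert_allclose(phen, genetic_values(pop, arch))

    def test_heritability_calibration(self, rng):
        pop, arch = generate_initial_population(SimConfig(k0=4000), rng)
        cfg = SimConfig(k0=4000, heritability=0.5)
        eff = derive_effects(pop, arch, cfg)
        phen = simulate_phenotypes(pop, arch, eff, rng)
        gv = genetic_values(pop, arch)
        for j in range(3):
            ratio = np.var(gv[:, j]) / np.var(phen[:, j])
            assert 0.42 < ratio < 0.58

    def test_antagonistic_pleiotropy_negative_correlation(self, rng):
        pop, arch = generate_initial_population(SimConfig(k0=3000), rng)
        gv = genetic_values(pop, arch)
        assert np.corrcoef(gv[:, 0], gv[:, 2])[0, 1] < -0.1

    def test_all_desirable_is_maximal(self, rng):
        pop, arch = generate_initial_population(SimConfig(k0=20), rng)
        best = pop.alleles.copy()
        for t in arch.trait_ids:
            if t == "trait3":
                continue
            best[0, arch.qtl_indices[t], :] = arch.desirable_allele[t][:, None]
        pop.alleles = best
        gv = genetic_values(pop, arch)
        assert gv[0, 0] == gv[:, 0].max() == 2 * 40


class TestAdvanceGeneration:
    def test_population_size(self, rng):
        cfg = small_config()
        pop, arch = generate_initial_population(cfg, rng)
        plan = random_plan(pop, 8, rng)
        child = advance_generation(pop, plan, cfg, rng)
        assert child.n_individuals == 8 * 20

    def test_no_recombination_clones_homozygous_parents(self, rng):
        cfg = small_config(r_within=0.0, n_chromosomes=1)
        pop, arch = generate_initial_population(cfg, rng)
        pop.alleles[0] = 1  # fully homozygous desirable
        pop.alleles[1] = 1
        plan = random_plan(pop, 1, rng)
        plan.entries[0] = PlanEntry(0, 1, "a", "b", (), float("nan"))
        child = advance_generation(pop, plan, cfg, rng)
        assert (child.alleles == 1).all()

    def test_neutral_mating_conserves_frequencies(self, rng):
        cfg = small_config(k0=500, progeny_per_cross=50)
        pop, arch = generate_initial_population(cfg, rng)
        plan = random_plan(pop, 40, rng)
        child = advance_generation(pop, plan, cfg, rng)
        parents = np.unique([[e.parent1, e.parent2] for e in plan])
        parent_freq = pop.alleles[parents].mean()
        child_freq = child.alleles.mean()
        se = np.sqrt(0.25 / (2 * child.n_individuals))
        # offspring allele frequency fluctuates around the selected parents' mean
        assert abs(child_freq - parent_freq) < 4 * se

    def test_empty_plan_rejected(self, rng):
        cfg = small_config()
        pop, _ = generate_initial_population(cfg, rng)
        with pytest.raises(ValueError, match="empty"):
            advance_generation(pop, CrossingPlan(), cfg, rng)


class TestScenario:
    def test_reproducibility_bitwise(self):
        cfg = small_config(replications=1)
        a = run_scenario("ecv", cfg)
        b = run_scenario("ecv", cfg)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.relatedness, b.relatedness)

    def test_metrics_shape(self):
        cfg = small_config(replications=2)
        res = run_scenario("phenotypic", cfg)
        # (generations + 1) snapshots x 3 traits x replications
        assert len(res.metrics) == 2 * 5 * 3
        assert len(res.relatedness) == 2 * 4
        assert set(res.metrics["trait"]) == {"trait1", "trait2", "trait3"}

    def test_scenario_presets(self):
        assert scenario_config("A").pairs_per_generation == SCENARIO_PAIRS["A"]
        assert scenario_config("b").pairs_per_generation == (50, 10, 5, 5)
        with pytest.raises(ValueError):
            scenario_config("Z")

    def test_single_trait_ecv_improves_target(self):
        cfg = small_config(k0=400, replications=3, trait_priority=("trait1",))
        res = run_scenario("ecv", cfg)
        m = res.metrics[res.metrics["trait"] == "trait1"]
        by_gen = m.groupby("generation")["allele_freq"].mean()
        assert by_gen.iloc[-1] > by_gen.iloc[0] + 0.05

    def test_gebv_method_runs_and_records_relatedness(self):
        cfg = small_config(replications=1)
        res = run_scenario("gebv", cfg)
        assert np.isfinite(res.relatedness["mean_g"]).all()
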
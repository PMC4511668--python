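"""Forward simulation: sampling laws, invariants and the host genealogy."""

import numpy as np
import pytest

from micronull import (
    EnvironmentState,
    GenealogyRecord,
    PopulationState,
    SimulationConfig,
    compose_environment,
    initialize_population,
    mrca_generation,
    population_richness,
    run_simulation,
    sample_offspring_microbiome,
    step_generation,
)
from micronull.simulation import diversity_record, trajectory_frame


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(parental_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(pooled_env_fraction=-0.1)

    def test_positive_counts_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(num_hosts=0)
        with pytest.raises(ValueError):
            SimulationConfig(num_taxa=0)

    def test_yaml_roundtrip(self, tmp_path, tiny_config):
        path = tmp_path / "config.yaml"
        tiny_config.to_yaml(path)
        loaded = SimulationConfig.from_yaml(path)
        assert loaded == tiny_config
        overridden = SimulationConfig.from_yaml(path, seed=7)
        assert overridden.seed == 7

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("num_hosts: 5\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            SimulationConfig.from_yaml(path)


class TestInitialization:
    def test_single_taxon_fills_every_slot(self, rng):
        cfg = SimulationConfig(num_hosts=5, slots_per_host=10, num_taxa=1)
        pop = initialize_population(cfg, rng)
        assert (pop.counts == 10).all()

    def test_rows_sum_to_slot_capacity(self, rng, tiny_config):
        pop = initialize_population(tiny_config, rng)
        assert (pop.counts.sum(axis=1) == tiny_config.slots_per_host).all()
        assert pop.generation == 0

    def test_uniform_seeding_moments(self, rng):
        # multinomial: mean n/m = 2500, sd = sqrt(n p (1-p)) ~ 43.3
        cfg = SimulationConfig(num_hosts=1, slots_per_host=10_000, num_taxa=4)
        pop = initialize_population(cfg, rng)
        sd = np.sqrt(10_000 * 0.25 * 0.75)
        assert (np.abs(pop.counts[0] - 2500) < 4 * sd).all()


class TestComposeEnvironment:
    def _pop(self, counts):
        return PopulationState(np.asarray(counts))

    def test_y_zero_returns_fixed_exactly(self):
        fixed = np.array([0.7, 0.3])
        pop = self._pop([[10, 0], [10, 0]])
        np.testing.assert_array_equal(compose_environment(pop, fixed, 0.0), fixed)

    def test_y_one_returns_pool_of_identical_hosts(self):
        pop = self._pop([[6, 4], [6, 4]])
        result = compose_environment(pop, np.array([0.5, 0.5]), 1.0)
        np.testing.assert_allclose(result, [0.6, 0.4])

    def test_convex_combination(self):
        pop = self._pop([[10, 0]])
        result = compose_environment(pop, np.array([0.5, 0.5]), 0.5)
        np.testing.assert_allclose(result, [0.75, 0.25])

    def test_result_sums_to_one(self, rng):
        counts = rng.integers(0, 9, size=(4, 6)) + 1
        out = compose_environment(self._pop(counts), np.full(6, 1 / 6), 0.37)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_y_outside_unit_interval(self):
        with pytest.raises(ValueError):
            compose_environment(self._pop([[1, 1]]), np.array([0.5, 0.5]), 1.2)


class TestOffspringSampling:
    def test_pure_parental_support_subset(self, rng):
        parent = np.array([0, 30, 0, 70, 0])
        env = np.full(5, 0.2)
        child = sample_offspring_microbiome(parent, env, 1.0, 100, rng)
        assert child.sum() == 100
        assert (child[parent == 0] == 0).all()

    def test_pure_environmental_moments(self, rng):
        env = np.array([0.9, 0.1])
        child = sample_offspring_microbiome(np.array([5, 5]), env, 0.0, 10_000, rng)
        sd = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(child[0] - 9000) < 4 * sd

    def test_parental_fraction_mean(self, rng):
        # parent carries only taxon 0; env splits evenly; with x = 0.3 the
        # expected taxon-1 count is slots * 0.7 * 0.5
        parent = np.array([50, 0])
        env = np.array([0.5, 0.5])
        reps = 1000
        slots = 1000
        taxon1 = np.array(
            [
                sample_offspring_microbiome(parent, env, 0.3, slots, rng)[1]
                for _ in range(reps)
            ]
        )
        expected = slots * 0.7 * 0.5
        se = np.sqrt(slots * 0.35 * 0.65 / reps)
        assert abs(taxon1.mean() - expected) < 4 * se

    def test_rejects_x_outside_unit_interval(self, rng):
        with pytest.raises(ValueError):
            sample_offspring_microbiome(np.array([1, 1]), np.array([0.5, 0.5]),
                                        1.3, 10, rng)


class TestStepGeneration:
    def test_invariants_preserved(self, rng, tiny_config):
        pop = initialize_population(tiny_config, rng)
        fixed = tiny_config.fixed_env()
        env = EnvironmentState(fixed.copy(), fixed.copy())
        for _ in range(5):
            pop = step_generation(pop, env, tiny_config, rng)
            assert (pop.counts.sum(axis=1) == tiny_config.slots_per_host).all()
            assert (pop.counts >= 0).all()
            assert pop.parent_index.min() >= 0
            assert pop.parent_index.max() < tiny_config.num_hosts
            assert env.current_distribution.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_host_pure_parental_is_absorbing(self, rng):
        cfg = SimulationConfig(num_hosts=1, slots_per_host=20, num_taxa=3,
                               parental_fraction=1.0)
        pop = PopulationState(np.array([[20, 0, 0]]), generation=0)
        env = EnvironmentState(np.full(3, 1 / 3), np.full(3, 1 / 3))
        for _ in range(3):
            pop = step_generation(pop, env, cfg, rng)
        np.testing.assert_array_equal(pop.counts, [[20, 0, 0]])

    def test_pure_parental_law_independent_of_environment_model(self):
        """With x=1 the environment contributes nothing: FE, ME and PE runs
        must agree distributionally (means over seeded replicates)."""
        means = {}
        for y in (0.0, 0.5, 1.0):
            finals = []
            for rep in range(12):
                cfg = SimulationConfig(
                    num_hosts=25, slots_per_host=50, num_taxa=6,
                    parental_fraction=1.0, pooled_env_fraction=y,
                    max_generations=80, record_interval=80, seed=500 + rep,
                )
                res = run_simulation(cfg)
                finals.append(res.trajectory[-1].gamma)
            means[y] = (np.mean(finals), np.std(finals, ddof=1) / np.sqrt(12))
        for y in (0.5, 1.0):
            diff = abs(means[y][0] - means[0.0][0])
            se = np.hypot(means[y][1], means[0.0][1])
            assert diff < 4 * max(se, 1e-3)


class TestRunSimulation:
    def test_seeded_runs_are_bitwise_identical(self, tiny_config):
        a = run_simulation(tiny_config)
        b = run_simulation(tiny_config)
        np.testing.assert_array_equal(a.final_state.counts, b.final_state.counts)
        assert a.trajectory == b.trajectory
        for pa, pb in zip(a.genealogy.parents, b.genealogy.parents):
            np.testing.assert_array_equal(pa, pb)

    def test_different_seeds_differ(self, tiny_config):
        a = run_simulation(tiny_config)
        b = run_simulation(tiny_config.replace(seed=tiny_config.seed + 1))
        assert (a.final_state.counts != b.final_state.counts).any()

    def test_pure_parental_absorbs_to_single_taxon(self):
        cfg = SimulationConfig(
            num_hosts=30, slots_per_host=40, num_taxa=6, parental_fraction=1.0,
            max_generations=20_000, record_interval=500, seed=11,
            stop_on_absorption=True, track_genealogy=False,
        )
        res = run_simulation(cfg)
        assert population_richness(res.final_state) == 1

    def test_fixed_environment_retains_all_taxa(self):
        # extinction is impossible to sustain: every generation re-offers all
        # taxa through the fixed pool
        cfg = SimulationConfig(
            num_hosts=50, slots_per_host=100, num_taxa=20,
            parental_fraction=0.5, pooled_env_fraction=0.0,
            max_generations=1000, record_interval=250, seed=21,
            track_genealogy=False,
        )
        res = run_simulation(cfg)
        assert population_richness(res.final_state) == 20

    def test_taxa_are_exchangeable_under_neutrality(self):
        """No taxon is privileged: mean final abundances are all ~ 1/m."""
        m = 5
        finals = []
        for rep in range(40):
            cfg = SimulationConfig(
                num_hosts=20, slots_per_host=50, num_taxa=m,
                parental_fraction=0.6, pooled_env_fraction=0.5,
                max_generations=60, record_interval=60, seed=3000 + rep,
                track_genealogy=False,
            )
            res = run_simulation(cfg)
            pooled = res.final_state.counts.sum(axis=0)
            finals.append(pooled / pooled.sum())
        mean_ab = np.mean(finals, axis=0)
        se = np.std(finals, axis=0, ddof=1) / np.sqrt(len(finals))
        assert (np.abs(mean_ab - 1 / m) < 4 * np.maximum(se, 1e-3)).all()

    def test_stabilization_halts_early(self):
        cfg = SimulationConfig(
            num_hosts=20, slots_per_host=40, num_taxa=5,
            parental_fraction=0.0, pooled_env_fraction=0.0,
            max_generations=5000, record_interval=10,
            stop_on_stabilization=True, stabilization_window=10,
            stabilization_tolerance=1e-3, min_generations=100, seed=5,
            track_genealogy=False,
        )
        res = run_simulation(cfg)
        assert res.final_state.generation < 5000

    def test_trajectory_frame_columns(self, tiny_config):
        res = run_simulation(tiny_config)
        frame = trajectory_frame(res.trajectory)
        assert list(frame.columns) == [
            "generation", "alpha_mean", "alpha_sd", "beta", "gamma",
        ]
        assert frame["generation"].iloc[0] == 0


class TestGenealogy:
    def test_single_host_coalesces_immediately(self):
        genealogy = GenealogyRecord([np.array([0]), np.array([0])])
        assert mrca_generation(genealogy) == 1

    def test_shared_last_parent(self):
        genealogy = GenealogyRecord([np.array([0, 1, 2]), np.array([1, 1, 1])])
        assert mrca_generation(genealogy) == 1

    def test_no_coalescence_returns_none(self):
        # parent maps are permutations: lineages never merge
        genealogy = GenealogyRecord([np.arange(4) for _ in range(10)])
        assert mrca_generation(genealogy) is None

    def test_two_step_coalescence(self):
        # hosts -> parents {0,1}; those two share grandparent 3
        genealogy = GenealogyRecord(
            [np.array([3, 3, 2]), np.array([0, 0, 1]), np.array([0, 1, 1])]
        )
        assert mrca_generation(genealogy) == 2

    def test_empty_genealogy_rejected(self):
        with pytest.raises(ValueError):
            mrca_generation(GenealogyRecord([]))

    def test_one_parent_vector_per_generation(self, tiny_config):
        res = run_simulation(tiny_config)
        assert len(res.genealogy.parents) == res.final_state.generation
        for vec in res.genealogy.parents:
            assert vec.shape == (tiny_config.num_hosts,)


def test_diversity_record_uses_global_richness_by_default(rng):
    cfg = SimulationConfig(num_hosts=4, slots_per_host=30, num_taxa=10)
    pop = initialize_population(cfg, rng)
    rec = diversity_record(pop)
    assert 0.0 <= rec.alpha_mean <= 1.0
    assert 0.0 <= rec.gamma <= 1.0
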
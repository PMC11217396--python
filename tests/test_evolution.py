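"""GA engine: mutation, selection, generation stepping, full runs."""

import numpy as np
import pytest

from bowtie_evo.evolution import (
    EvolutionConfig,
    NetworkInit,
    evolve_ensemble,
    expand_network,
    generation_step,
    instantaneous_min_waist,
    mutate,
    regularized_fitness,
    run_evolution,
    tournament_select,
)
from bowtie_evo.goals import generate_goal
from bowtie_evo.network import LayeredNetwork, compose, fitness, init_network


class TestMutate:
    def test_forced_unit_multiplier_is_identity(self, rng):
        net = init_network(4, 3, 1.0, rng)
        out = mutate(net, rng, _forced_xi=1.0)
        np.testing.assert_array_equal(out.matrices, net.matrices)

    def test_changes_exactly_one_entry(self, rng):
        net = init_network(4, 3, 1.0, rng)
        out = mutate(net, rng)
        assert np.sum(out.matrices != net.matrices) == 1

    def test_multiplier_moments_match_declared_distribution(self):
        from bowtie_evo.evolution import _draw_xi

        xi = _draw_xi(np.random.default_rng(0), (100_000,), 1.0, 0.1, True)
        assert xi.mean() == pytest.approx(1.0, abs=0.01)
        assert xi.var() == pytest.approx(0.1, rel=0.05)
        assert np.all(xi > 0)


class TestSelection:
    def test_dominant_individual_fills_all_slots(self, rng):
        nets = [init_network(2, 2, 1.0, rng) for _ in range(6)]
        fits = [-10.0, -10.0, -1.0, -10.0, -10.0, -10.0]
        sel = tournament_select(nets, fits, group_size=6, rng=rng, n_select=4)
        for s in sel:
            np.testing.assert_array_equal(s.matrices, nets[2].matrices)

    def test_selection_pressure_raises_mean_fitness(self, rng):
        fits = np.linspace(-100, 0, 20)
        pool_mean = fits.mean()
        means = []
        for _ in range(300):
            nets = [LayeredNetwork(np.full((1, 1, 1), i + 1.0)) for i in range(20)]
            sel = tournament_select(nets, fits, 4, rng, n_select=10)
            idx = [int(s.matrices[0, 0, 0]) - 1 for s in sel]
            means.append(fits[idx].mean())
        assert np.mean(means) > pool_mean

    def test_equal_fitness_returns_members_of_pool(self, rng):
        nets = [LayeredNetwork(np.full((1, 1, 1), i + 1.0)) for i in range(8)]
        sel = tournament_select(nets, [0.0] * 8, 4, rng, n_select=4)
        assert len(sel) == 4
        vals = {s.matrices[0, 0, 0] for s in sel}
        assert vals <= {float(i + 1) for i in range(8)}


class TestRegularizedFitness:
    def test_zero_lambda_equals_fitness(self, rng):
        net = init_network(3, 2, 1.0, rng)
        g = generate_goal(3, 1, 2.0, rng)
        assert regularized_fitness(net, g, "L1", 0.0) == pytest.approx(fitness(net, g))

    @pytest.mark.parametrize("kind", ["L1", "L2"])
    def test_all_ones_stack_penalty_is_link_count(self, kind):
        net = LayeredNetwork(np.ones((2, 2, 2)))
        g = generate_goal(2, 1, 1.0, np.random.default_rng(0))
        base = fitness(net, g)
        assert regularized_fitness(net, g, kind, 1.0) == pytest.approx(base - 8.0)

    def test_negative_lambda_rejected(self, rng):
        net = init_network(2, 2, 1.0, rng)
        with pytest.raises(ValueError):
            regularized_fitness(net, np.zeros((2, 2)), "L1", -1.0)


class TestGenerationStep:
    def test_noop_configuration_preserves_population(self, rng):
        cfg = EvolutionConfig(N=8, mutate_fraction=0.0, selection="elite")
        pop = [init_network(3, 2, 1.0, rng) for _ in range(8)]
        g = generate_goal(3, 1, 2.0, rng)
        new, stats = generation_step(pop, g, cfg, rng)
        old = sorted(fitness(p, g) for p in pop)
        now = sorted(fitness(p, g) for p in new)
        np.testing.assert_allclose(now, old, rtol=1e-12)
        assert stats["evaluations"] == 16

    def test_elite_mean_fitness_is_monotone(self, rng):
        # parents preserved (copies-only mutation) so elite survivors can
        # never lose ground
        cfg = EvolutionConfig(
            N=10, selection="elite", seed=3, mutate_pool="copies"
        )
        g = generate_goal(3, 1, 5.0, rng)
        pop = [init_network(3, 2, 0.5, rng) for _ in range(10)]
        last = -np.inf
        for _ in range(100):
            pop, stats = generation_step(pop, g, cfg, rng)
            assert stats["mean_fitness"] >= last - 1e-9
            last = stats["mean_fitness"]


class TestRunEvolution:
    def test_preadapted_population_converges_immediately(self, rng):
        g = generate_goal(3, 1, 2.0, rng)
        perfect = LayeredNetwork(np.stack([g.entries, np.eye(3)]))
        cfg = EvolutionConfig(N=10, seed=0, max_generations=100)
        traj = run_evolution(cfg, g, perfect)
        assert traj.converged_at == 0
        assert traj.best_fitness[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_seeds_reproduce_trajectories_exactly(self, rng):
        g = generate_goal(4, 1, 10.0, rng)
        cfg = EvolutionConfig(N=20, seed=11, max_generations=300, record_stride=10)
        t1 = run_evolution(cfg, g, NetworkInit(4, 3, 0.1), stop_on_convergence=False)
        t2 = run_evolution(cfg, g, NetworkInit(4, 3, 0.1), stop_on_convergence=False)
        np.testing.assert_array_equal(t1.mean_fitness, t2.mean_fitness)
        np.testing.assert_array_equal(t1.waist, t2.waist)
        np.testing.assert_array_equal(
            t1.final_network.matrices, t2.final_network.matrices
        )

    def test_best_never_below_mean_and_fitness_nonpositive(self, rng):
        g = generate_goal(4, 2, 10.0, rng)
        cfg = EvolutionConfig(N=20, seed=2, max_generations=500, record_stride=20)
        traj = run_evolution(cfg, g, NetworkInit(4, 3, 0.1), stop_on_convergence=False)
        assert np.all(traj.best_fitness >= traj.mean_fitness - 1e-12)
        assert np.all(traj.best_fitness <= 0.0)

    def test_nonconvergence_reports_none(self, rng):
        g = generate_goal(6, 6, 60.0, rng)
        cfg = EvolutionConfig(N=10, seed=1, max_generations=50)
        traj = run_evolution(cfg, g, NetworkInit(6, 4, 0.01))
        assert traj.converged_at is None

    def test_rank1_small_A0_run_becomes_bowtie(self):
        # end-to-end at study conditions (single replicate)
        g = generate_goal(6, 1, 60.0, np.random.default_rng(5))
        cfg = EvolutionConfig(seed=5, max_generations=20_000)
        traj = run_evolution(cfg, g, NetworkInit(6, 4, 0.01))
        assert traj.converged_at is not None
        assert traj.waist[-1] < 6


class TestEnsemble:
    def test_goal_switch_reevaluates_fitness(self, rng):
        g1 = generate_goal(3, 1, 2.0, rng)
        g2 = generate_goal(3, 1, 8.0, rng)
        perfect = LayeredNetwork(np.stack([g1.entries, np.eye(3)]))
        cfg = EvolutionConfig(
            N=10, seed=0, max_generations=40, record_stride=5, mutate_fraction=0.0
        )
        traj = run_evolution(
            cfg,
            [(0, g1), (20, g2)],
            perfect,
            stop_on_convergence=False,
        )
        i_pre = np.searchsorted(traj.generations, 20) - 1
        assert traj.best_fitness[i_pre] == pytest.approx(0.0, abs=1e-12)
        assert traj.best_fitness[-1] < -1.0  # goal moved away

    def test_mutation_disabled_elite_keeps_population(self, rng):
        g = generate_goal(3, 2, 4.0, rng)
        cfg = EvolutionConfig(
            N=6, seed=4, mutate_fraction=0.0, selection="elite", record_stride=10
        )
        init = np.stack([init_network(3, 2, 1.0, rng).matrices for _ in range(6)])
        traj = run_evolution(
            cfg, g, init, n_generations=50, stop_on_convergence=False
        )
        assert np.all(traj.mean_fitness == traj.mean_fitness[0])


class TestExpandNetwork:
    def test_original_block_preserved_and_padding_bounded(self, rng):
        net = init_network(10, 4, 10.0, rng)
        big = expand_network(net, 20, 1e-3, rng)
        np.testing.assert_array_equal(big.matrices[:, :10, :10], net.matrices)
        pad = big.matrices[:, 10:, :]
        assert np.all(pad >= 0) and np.all(pad < 1e-3)

    def test_vanishing_padding_preserves_composition(self, rng):
        net = init_network(5, 3, 2.0, rng)
        big = expand_network(net, 8, 1e-12, rng)
        np.testing.assert_allclose(
            compose(big)[:5, :5], compose(net), rtol=1e-9
        )

    def test_errors(self, rng):
        net = init_network(5, 3, 2.0, rng)
        with pytest.raises(ValueError):
            expand_network(net, 4, 1e-3, rng)
        with pytest.raises(ValueError):
            expand_network(net, 8, 0.0, rng)


def test_instantaneous_min_waist():
    assert instantaneous_min_waist(np.array([6, 6, 6])) == 6
    assert instantaneous_min_waist(np.array([6, 3, 1, 6])) == 1
    with pytest.raises(ValueError):
        instantaneous_min_waist(np.array([]))


def test_config_validation():
    with pytest.raises(ValueError):
        EvolutionConfig(N=1)
    with pytest.raises(ValueError):
        EvolutionConfig(selection="roulette")
    with pytest.raises(ValueError):
        EvolutionConfig(reg_lambda=-0.1)
    with pytest.raises(ValueError):
        EvolutionConfig(tournament_size=1)
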
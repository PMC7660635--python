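"""Ant colony search: edge rules, pheromone updates, GA engine, full runs."""

import numpy as np
import pytest

from antsel.heuristics import HeuristicVector
from antsel.search import (
    AntState,
    SearchConfig,
    PheromoneGraph,
    choose_edge,
    construct_tour,
    deposit,
    ga_evolve,
    global_update,
    local_update,
    run,
    transition_probability,
)


def make_graph(n=5, eta=None, tau=None, **kwargs):
    if eta is None:
        eta = np.ones(n)
    hv = HeuristicVector("PCC", np.asarray(eta, dtype=float),
                         float(np.mean(eta)))
    if tau is None:
        tau = np.ones((len(eta), 2))
    return PheromoneGraph(tau=np.asarray(tau, dtype=float), eta=hv, **kwargs)


class TestTransitionProbability:
    def test_symmetric_graph_is_even(self):
        g = make_graph(3)
        assert transition_probability(g, 0) == pytest.approx((0.5, 0.5))

    def test_double_importance_two_thirds(self):
        # equal pheromone, feature importance twice the average, alpha=beta=1
        g = make_graph(eta=[2.0, 0.5, 0.5, 0.5], alpha=1.0, beta=1.0)
        g.eta = HeuristicVector("PCC", np.array([2.0, 1.0, 1.0, 1.0]), 1.0)
        p0, p1 = transition_probability(g, 0)
        assert p1 == pytest.approx(2 / 3)

    def test_pheromone_skew_with_exponents(self):
        g = make_graph(n=1, eta=[1.0], tau=[[1.0, 4.0]], alpha=0.8, beta=2.0)
        _, p1 = transition_probability(g, 0)
        assert p1 == pytest.approx(4**0.8 / (1 + 4**0.8))

    def test_probabilities_sum_to_one_randomized(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            g = make_graph(
                n=n,
                eta=rng.uniform(1e-6, 5.0, n),
                tau=rng.uniform(1e-6, 10.0, (n, 2)),
                alpha=float(rng.uniform(0, 3)),
                beta=float(rng.uniform(0, 3)),
            )
            for i in range(n):
                p0, p1 = transition_probability(g, i)
                assert p0 + p1 == pytest.approx(1.0, abs=1e-12)
                assert p0 >= 0 and p1 >= 0


class TestChooseEdge:
    def test_full_rule_q0_one_always_skips(self):
        g = make_graph(q0=1.0)
        rng = np.random.default_rng(0)
        assert all(
            choose_edge(g, 0, "full_pseudo_random", rng) == 0 for _ in range(200)
        )

    def test_full_rule_gate_composition(self):
        # symmetric graph: P(select) = (1 - q0) * 0.5 = 0.325 at q0 = 0.35
        g = make_graph(q0=0.35)
        rng = np.random.default_rng(1)
        n = 100_000
        hits = sum(choose_edge(g, 0, "full_pseudo_random", rng) for _ in range(n))
        p = 0.325
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_full_rule_q0_zero_matches_binary_distribution(self):
        g = make_graph(q0=0.0)
        rng = np.random.default_rng(2)
        n = 50_000
        full = sum(choose_edge(g, 0, "full_pseudo_random", rng) for _ in range(n))
        binary = sum(choose_edge(g, 0, "binary", rng) for _ in range(n))
        sigma = np.sqrt(0.25 / n)
        assert abs(full / n - 0.5) < 4 * sigma
        assert abs(binary / n - 0.5) < 4 * sigma

    def test_pseudo_random_rule_is_greedy_under_gate(self):
        # q0=1 forces the greedy branch: picks the edge with larger weight
        g = make_graph(n=2, eta=[5.0, 5.0], tau=[[1.0, 1.0], [1.0, 1.0]], q0=1.0)
        g.eta = HeuristicVector("PCC", np.array([5.0, 0.01]), 1.0)
        rng = np.random.default_rng(3)
        assert choose_edge(g, 0, "pseudo_random", rng) == 1  # eta >> eta0
        assert choose_edge(g, 1, "pseudo_random", rng) == 0  # eta << eta0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            choose_edge(make_graph(), 0, "roulette", np.random.default_rng(0))


class TestPheromoneUpdates:
    def test_local_update_fixed_point(self):
        g = make_graph(tau=np.full((5, 2), 1.0), tau0=1.0, rho=0.2)
        local_update(g, 2, 1)
        assert g.tau[2, 1] == pytest.approx(1.0)

    def test_local_update_hand_case(self):
        g = make_graph(tau=np.full((5, 2), 2.0), tau0=1.0, rho=0.2)
        local_update(g, 0, 1)
        assert g.tau[0, 1] == pytest.approx(1.8)
        assert g.tau[0, 0] == 2.0  # untouched

    def test_local_update_contracts_to_tau0(self):
        g = make_graph(n=1, eta=[1.0], tau=np.full((1, 2), 50.0), tau0=1.0, rho=0.2)
        for _ in range(200):
            local_update(g, 0, 0)
        assert g.tau[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_deposit_hand_case(self):
        best = AntState(np.array([1] * 50 + [0] * 150), fitness=0.5)
        assert deposit(best, 200) == pytest.approx(1.25)

    def test_deposit_boundary_full_subset(self):
        best = AntState(np.ones(10, dtype=int), fitness=1.0)
        assert deposit(best, 10) == pytest.approx(1.0)

    def test_deposit_decreases_with_subset_size(self):
        prev = np.inf
        for n_sel in (1, 5, 20, 60, 100):
            best = AntState(
                np.array([1] * n_sel + [0] * (100 - n_sel)), fitness=0.4
            )
            d = deposit(best, 100)
            assert d < prev
            prev = d

    def test_global_update_hand_case(self):
        g = make_graph(n=4, tau=np.ones((4, 2)), rho=0.2, tau0=1.0)
        best = AntState(np.array([1, 0, 0, 0]), fitness=0.5)
        # deposit = 0.5 + (1 - 1/4) = 1.25; updated edge = 0.8 + 1.25
        global_update(g, best)
        assert g.tau[0, 1] == pytest.approx(2.05)
        assert g.tau[0, 0] == pytest.approx(0.8)
        assert g.tau[1, 1] == pytest.approx(0.8)

    def test_global_update_empty_best_pure_evaporation(self):
        g = make_graph(n=3, tau=np.full((3, 2), 2.0), rho=0.2)
        best = AntState(np.zeros(3, dtype=int), fitness=-1.0)
        global_update(g, best)
        assert np.allclose(g.tau, 1.6)

    def test_negative_deposit_hits_floor(self):
        g = make_graph(n=2, tau=np.full((2, 2), 0.5), rho=0.2, tau0=1.0)
        best = AntState(np.ones(2, dtype=int), fitness=-0.9)
        # deposit = -0.9 + 0 = -0.9; 0.4 - 0.9 < 0 -> floored
        global_update(g, best)
        assert np.all(g.tau > 0)
        assert g.tau[0, 1] == pytest.approx(g.tau_min)

    def test_floor_invariant_under_random_update_sequences(self):
        rng = np.random.default_rng(9)
        g = make_graph(n=6, rho=0.3)
        for _ in range(300):
            if rng.random() < 0.7:
                local_update(g, int(rng.integers(6)), int(rng.integers(2)))
            else:
                subset = (rng.random(6) < 0.5).astype(int)
                fit = float(rng.uniform(-1, 1))
                global_update(g, AntState(subset, fit))
        assert np.all(g.tau >= g.tau_min)


class TestConstructTour:
    def test_tour_covers_all_features(self):
        g = make_graph(n=200)
        ant = construct_tour(g, rng=np.random.default_rng(0))
        assert len(ant.subset) == 200
        assert ant.n_selected == int(ant.subset.sum())

    def test_q0_one_selects_nothing(self):
        g = make_graph(n=20, q0=1.0)
        ant = construct_tour(g, rng=np.random.default_rng(1))
        assert ant.n_selected == 0

    def test_same_rng_state_same_tour(self):
        ant1 = construct_tour(make_graph(n=30), rng=np.random.default_rng(5))
        ant2 = construct_tour(make_graph(n=30), rng=np.random.default_rng(5))
        assert np.array_equal(ant1.subset, ant2.subset)

    def test_local_updates_applied_during_tour(self):
        g = make_graph(n=10, tau=np.full((10, 2), 3.0), tau0=1.0, rho=0.2)
        construct_tour(g, rng=np.random.default_rng(2))
        # exactly one edge per feature decayed toward tau0
        changed = np.sum(~np.isclose(g.tau, 3.0))
        assert changed == 10

    def test_batched_mode_same_subset_distribution_shape(self):
        g = make_graph(n=10)
        ant = construct_tour(
            g, rng=np.random.default_rng(3), batched_local_updates=True
        )
        assert len(ant.subset) == 10


def onemax(subset):
    return float(np.sum(subset)) / len(subset)


class TestGaEvolve:
    def test_no_operators_resamples_inputs(self):
        rng = np.random.default_rng(0)
        colony = [AntState((rng.random(12) < 0.5).astype(int)) for _ in range(8)]
        for a in colony:
            a.fitness = onemax(a.subset)
        cfg = SearchConfig(
            ga_generations=1, ga_population=8, crossover_rate=0.0,
            mutation_rate=0.0,
        )
        out = ga_evolve(colony, cfg, onemax, np.random.default_rng(1))
        inputs = {a.subset.tobytes() for a in colony}
        assert all(a.subset.tobytes() in inputs for a in out)
        assert max(a.fitness for a in out) >= max(a.fitness for a in colony)

    def test_onemax_improves_in_most_seeds(self):
        improved = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            colony = [AntState((rng.random(20) < 0.5).astype(int)) for _ in range(30)]
            for a in colony:
                a.fitness = onemax(a.subset)
            start = max(a.fitness for a in colony)
            cfg = SearchConfig(ga_generations=10, ga_population=30)
            out = ga_evolve(colony, cfg, onemax, rng)
            improved += int(max(a.fitness for a in out) > start)
        assert improved >= 45  # >= 90% of seeds

    def test_degenerate_population_fixed_without_mutation(self):
        base = np.array([1, 0, 1, 0, 1], dtype=int)
        colony = [AntState(base.copy(), onemax(base)) for _ in range(6)]
        cfg = SearchConfig(ga_generations=3, ga_population=6, mutation_rate=0.0)
        out = ga_evolve(colony, cfg, onemax, np.random.default_rng(2))
        assert all(np.array_equal(a.subset, base) for a in out)


class TestRun:
    def test_deterministic_under_seed(self):
        eta = HeuristicVector("PCC", np.linspace(0.1, 1.0, 15), 0.55)
        cfg = SearchConfig(n_ants=6, n_iterations=4, ga_generations=3,
                        ga_population=6, seed=77)
        a = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=15)
        b = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=15)
        assert np.array_equal(a.best_subset, b.best_subset)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history

    def test_incumbent_fitness_monotone(self):
        eta = HeuristicVector("PCC", np.linspace(0.1, 1.0, 20), 0.55)
        cfg = SearchConfig(n_ants=8, n_iterations=8, ga_generations=2,
                        ga_population=8, seed=3)
        res = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=20)
        trace = [h["best_fitness"] for h in res.history]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_finds_onemax_optimum(self):
        eta = HeuristicVector("PCC", np.ones(10), 1.0)
        cfg = SearchConfig(n_ants=10, n_iterations=8, ga_generations=5,
                        ga_population=10, seed=1, q0=0.1)
        res = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=10)
        assert res.best_fitness == 1.0
        assert res.n_selected == 10

    def test_q0_one_full_rule_yields_empty_subset_sentinel(self):
        eta = HeuristicVector("PCC", np.ones(8), 1.0)
        cfg = SearchConfig(n_ants=4, n_iterations=2, ga_generations=1,
                        ga_population=4, seed=0, q0=1.0, mutation_rate=0.0,
                        crossover_rate=0.0)
        res = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=8)
        assert res.n_selected == 0
        assert res.best_fitness == -1.0

    def test_evaluator_failure_carries_iteration_context(self):
        eta = HeuristicVector("PCC", np.ones(5), 1.0)

        def broken(subset):
            raise RuntimeError("boom")

        cfg = SearchConfig(n_ants=2, n_iterations=1, ga_generations=1,
                        ga_population=2, seed=0)
        with pytest.raises(RuntimeError, match="iteration 0"):
            run(heuristic=eta, cfg=cfg, evaluator=broken, n_features=5)

    def test_result_json_roundtrip(self, tmp_path):
        eta = HeuristicVector("PCC", np.ones(6), 1.0)
        cfg = SearchConfig(n_ants=4, n_iterations=2, ga_generations=2,
                        ga_population=4, seed=5)
        res = run(heuristic=eta, cfg=cfg, evaluator=onemax, n_features=6)
        import json

        payload = json.loads(res.to_json(tmp_path / "r.json",
                                         feature_names=[f"f{i}" for i in range(6)]))
        assert payload["n_selected"] == res.n_selected
        assert payload["config"]["n_ants"] == 4


class TestConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            SearchConfig(q0=1.5)
        with pytest.raises(ValueError):
            SearchConfig(crossover_rate=-0.1)

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            SearchConfig(n_ants=0)
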
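"""Reference feature-selection baselines for benchmarking the colony search.

Both baselines consume the same subset-fitness evaluator (cross-validated
MCC) as the main search, so comparisons isolate the search strategy.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from antsel._seeds import derive_seed
from antsel.search import AntState, SearchConfig, ga_evolve, _evaluate


def ga_select(
    evaluator: Callable[[np.ndarray], float],
    n_features: int,
    cfg: SearchConfig | None = None,
    seed: int = 0,
) -> AntState:
    """Plain genetic algorithm: random Bernoulli(0.5) initial population,
    then the same tournament/crossover/mutation/elitism engine as the
    aided search, with no pheromone or heuristic guidance."""
    cfg = cfg if cfg is not None else SearchConfig()
    rng = np.random.default_rng(derive_seed(seed, "ga_baseline"))
    init = [
        AntState((rng.random(n_features) < 0.5).astype(np.int8))
        for _ in range(cfg.ga_population)
    ]
    for ant in init:
        ant.fitness = _evaluate(ant, evaluator)
    final = ga_evolve(init, cfg, evaluator, rng)
    return max(final + init, key=lambda a: (a.fitness, -a.n_selected))


def sa_select(
    evaluator: Callable[[np.ndarray], float],
    n_features: int,
    n_steps: int = 300,
    t0: float = 0.2,
    cooling: float = 0.99,
    seed: int = 0,
) -> AntState:
    """Simulated annealing: single-bit-flip neighborhood, geometric cooling.

    Starts from a random Bernoulli(0.5) subset; each step flips one
    uniformly chosen bit, accepting improvements always and worsenings
    with probability exp(delta / T). The initial temperature (0.2) is on
    the order of typical MCC differences between neighboring subsets; the
    best state ever visited is returned.
    """
    if not (0.0 < cooling < 1.0):
        raise ValueError("cooling must be in (0, 1)")
    rng = np.random.default_rng(derive_seed(seed, "sa_baseline"))
    state = (rng.random(n_features) < 0.5).astype(np.int8)
    fit = _evaluate(AntState(state), evaluator)
    best = AntState(state.copy(), fit)
    temp = t0
    for _ in range(n_steps):
        i = int(rng.integers(0, n_features))
        cand = state.copy()
        cand[i] = 1 - cand[i]
        cand_fit = _evaluate(AntState(cand), evaluator)
        delta = cand_fit - fit
        if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-12)):
            state, fit = cand, cand_fit
            if fit > best.fitness or (
                fit == best.fitness and cand.sum() < best.n_selected
            ):
                best = AntState(state.copy(), fit)
        temp *= cooling
    return best
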
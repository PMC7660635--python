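"""GA-aided ant colony system for wrapper feature selection.

Feature selection is cast as a walk over a binary digraph: every feature
is a node with exactly two outgoing edges, *select* (E1) and *skip* (E0).
An ant visits the features in index order, picks one edge per node, and
its tour is the candidate subset. Edge choice combines learned pheromone
tau and a prior heuristic value eta:

    p(i, j) = tau[i,j]^alpha * eta[i,j]^beta /
              (tau[i,0]^alpha * eta0^beta + tau[i,1]^alpha * eta[i]^beta)

where eta[i] is the importance of feature i and eta0 the mean importance
of all features (the skip edge's heuristic). The *full pseudo-random
proportional rule* adds a sparsity gate: with probability q0 the skip
edge is taken outright, otherwise the proportional probability is
sampled — this halves the selected-subset size relative to the classical
pseudo-random rule without hurting fitness. Pheromone is updated locally
after each edge (decay toward tau0, encouraging exploration) and globally
once per iteration, depositing on the global best ant's selected edges an
amount that grows with its MCC and shrinks with its subset size. Between
tour construction and the global update, a genetic algorithm evolves the
ant population for a fixed number of generations; evolved ants compete
with the tours and the incumbent for global best, but the next colony is
always rebuilt from the pheromone graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from antsel._seeds import derive_seed
from antsel.evaluation import EMPTY_SUBSET_FITNESS, SubsetEvaluator
from antsel.heuristics import HeuristicVector, mdgi

RULES = ("binary", "pseudo_random", "full_pseudo_random")

TAU_MIN_REL = 1e-6  # pheromone floor, relative to tau0


@dataclass
class SearchConfig:
    """Search parameters; defaults follow the reference configuration
    (10 colony iterations of 30 ants; alpha 0.8, beta 2.0, tau0 1.0,
    evaporation 0.2, q0 0.35; GA: 30 chromosomes, 10 generations,
    crossover 0.7, mutation 0.1)."""

    n_ants: int = 30
    n_iterations: int = 10
    ga_generations: int = 10
    ga_population: int = 30
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    alpha: float = 0.8
    beta: float = 2.0
    tau0: float = 1.0
    rho: float = 0.2
    q0: float = 0.35
    seed: int = 0
    batched_local_updates: bool = False
    fitness_evaluator: Callable[[np.ndarray], float] | None = None

    def __post_init__(self):
        for name in ("crossover_rate", "mutation_rate", "rho", "q0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_ants", "n_iterations", "ga_generations", "ga_population"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "fitness_evaluator"
        }
        return d


@dataclass
class AntState:
    """One candidate subset: binary vector plus (optional) MCC fitness."""

    subset: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.subset = np.asarray(self.subset).astype(np.int8).ravel()
        if self.fitness is not None and not (-1.0 <= self.fitness <= 1.0):
            raise ValueError(f"fitness must be in [-1, 1], got {self.fitness}")

    @property
    def n_selected(self) -> int:
        return int(self.subset.sum())

    def copy(self) -> "AntState":
        return AntState(self.subset.copy(), self.fitness)


@dataclass
class PheromoneGraph:
    """Per-feature two-edge pheromone state. Column 0 is the skip edge E0,
    column 1 the select edge E1."""

    tau: np.ndarray  # (n, 2)
    eta: HeuristicVector
    alpha: float = 0.8
    beta: float = 2.0
    tau0: float = 1.0
    rho: float = 0.2
    q0: float = 0.35

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 2 or self.tau.shape[1] != 2:
            raise ValueError(f"tau must be (n, 2), got {self.tau.shape}")
        if self.tau.shape[0] != len(self.eta):
            raise ValueError("tau row count must match heuristic length")
        if np.any(self.tau <= 0):
            raise ValueError("pheromone must be strictly positive")

    @classmethod
    def from_config(cls, eta: HeuristicVector, cfg: SearchConfig) -> "PheromoneGraph":
        tau = np.full((len(eta), 2), cfg.tau0, dtype=float)
        return cls(
            tau=tau,
            eta=eta,
            alpha=cfg.alpha,
            beta=cfg.beta,
            tau0=cfg.tau0,
            rho=cfg.rho,
            q0=cfg.q0,
        )

    @property
    def n_features(self) -> int:
        return self.tau.shape[0]

    @property
    def tau_min(self) -> float:
        return TAU_MIN_REL * self.tau0

    def _weights(self, i: int) -> tuple[float, float]:
        w0 = self.tau[i, 0] ** self.alpha * self.eta.eta0**self.beta
        w1 = self.tau[i, 1] ** self.alpha * self.eta.eta[i] ** self.beta
        return w0, w1


def transition_probability(graph: PheromoneGraph, i: int) -> tuple[float, float]:
    """Edge probabilities (p_skip, p_select) for feature i.

    Both pheromone and heuristic values are strictly positive by
    construction, so the normalizer never vanishes and p0 + p1 == 1.
    """
    w0, w1 = graph._weights(i)
    total = w0 + w1
    return w0 / total, w1 / total


def choose_edge(
    graph: PheromoneGraph,
    i: int,
    rule: str = "full_pseudo_random",
    rng: np.random.Generator | None = None,
) -> int:
    """Pick edge 0 (skip) or 1 (select) for feature i under a transition rule.

    ``binary``             — always sample the proportional probability.
    ``pseudo_random``      — classical ACS: with probability q0 take the
                             greedy argmax of tau^alpha * eta^beta,
                             otherwise sample proportionally.
    ``full_pseudo_random`` — with probability q0 take the *skip* edge
                             outright (pruning redundant features),
                             otherwise sample proportionally.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    rng = rng if rng is not None else np.random.default_rng()
    if rule != "binary":
        q = rng.random()
        if q <= graph.q0:
            if rule == "full_pseudo_random":
                return 0
            w0, w1 = graph._weights(i)
            return int(w1 > w0)
    _, p1 = transition_probability(graph, i)
    return int(rng.random() < p1)


def local_update(graph: PheromoneGraph, i: int, j: int) -> None:
    """Decay the just-traversed edge toward tau0:
    tau <- (1 - rho) * tau + rho * tau0. In-place; only edge (i, j) changes."""
    graph.tau[i, j] = (1.0 - graph.rho) * graph.tau[i, j] + graph.rho * graph.tau0


def construct_tour(
    graph: PheromoneGraph,
    rule: str = "full_pseudo_random",
    rng: np.random.Generator | None = None,
    batched_local_updates: bool = False,
) -> AntState:
    """Walk all features in index order, choosing one edge per node.

    By default each edge choice immediately applies the local pheromone
    update (visible to later choices and later ants in the same
    iteration); with ``batched_local_updates`` the updates are applied
    together after the tour completes.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = graph.n_features
    subset = np.zeros(n, dtype=np.int8)
    chosen: list[tuple[int, int]] = []
    for i in range(n):
        j = choose_edge(graph, i, rule, rng)
        subset[i] = j
        if batched_local_updates:
            chosen.append((i, j))
        else:
            local_update(graph, i, j)
    for i, j in chosen:
        local_update(graph, i, j)
    return AntState(subset=subset)


def deposit(best: AntState, n: int) -> float:
    """Pheromone laid on each selected edge of the global best ant:
    its MCC plus a parsimony bonus (1 - subset_size / n_features)."""
    if best.fitness is None:
        raise ValueError("best ant has no fitness")
    if best.n_selected < 1:
        raise ValueError("deposit requires a non-empty subset")
    return best.fitness + (1.0 - best.n_selected / n)


def global_update(graph: PheromoneGraph, best: AntState) -> None:
    """Evaporate every edge by (1 - rho); add the deposit to the select
    edges of the best ant's features. A negative-MCC best can make the
    deposit negative and actively drain those edges; the floor
    tau_min = 1e-6 * tau0 keeps every pheromone strictly positive."""
    graph.tau *= 1.0 - graph.rho
    if best.n_selected >= 1:
        delta = deposit(best, graph.n_features)
        sel = best.subset.astype(bool)
        graph.tau[sel, 1] += delta
    np.maximum(graph.tau, graph.tau_min, out=graph.tau)


# ---------------------------------------------------------------------------
# GA refinement
# ---------------------------------------------------------------------------

def _evaluate(ant: AntState, evaluator: Callable[[np.ndarray], float]) -> float:
    if ant.n_selected == 0:
        return EMPTY_SUBSET_FITNESS
    return float(evaluator(ant.subset))


def _tournament(
    fits: np.ndarray, rng: np.random.Generator, size: int = 2
) -> int:
    contenders = rng.integers(0, len(fits), size=size)
    return int(contenders[np.argmax(fits[contenders])])


def ga_evolve(
    colony: Sequence[AntState],
    cfg: SearchConfig,
    fitness_evaluator: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> list[AntState]:
    """Evolve the evaluated ant colony for cfg.ga_generations.

    Tournament selection (size 2), single-point crossover at
    cfg.crossover_rate, per-bit flip mutation at cfg.mutation_rate divided
    by chromosome length, elitism carrying the best individual unchanged
    into each next generation. Returns the final population with
    fitnesses; the caller decides what to do with it (in the full search
    the evolved ants only compete for global best).
    """
    if not colony:
        raise ValueError("empty colony")
    n = len(colony[0].subset)
    pop = np.stack([a.subset for a in colony]).astype(np.int8)
    fits = np.array(
        [
            a.fitness if a.fitness is not None else _evaluate(a, fitness_evaluator)
            for a in colony
        ],
        dtype=float,
    )
    size = cfg.ga_population
    if len(pop) != size:
        # resize by fitness-biased resampling (tournament with replacement)
        idx = [_tournament(fits, rng) for _ in range(size)]
        pop, fits = pop[idx], fits[idx]

    per_bit = cfg.mutation_rate / n
    for _ in range(cfg.ga_generations):
        elite = int(np.argmax(fits))
        new_pop = [pop[elite].copy()]
        while len(new_pop) < size:
            a = pop[_tournament(fits, rng)]
            b = pop[_tournament(fits, rng)]
            if rng.random() < cfg.crossover_rate and n > 1:
                point = int(rng.integers(1, n))
                c1 = np.concatenate([a[:point], b[point:]])
                c2 = np.concatenate([b[:point], a[point:]])
            else:
                c1, c2 = a.copy(), b.copy()
            for child in (c1, c2):
                if len(new_pop) >= size:
                    break
                if per_bit > 0:
                    flips = rng.random(n) < per_bit
                    child = np.where(flips, 1 - child, child).astype(np.int8)
                new_pop.append(child)
        pop = np.stack(new_pop)
        fits = np.array(
            [_evaluate(AntState(ind), fitness_evaluator) for ind in pop]
        )
    return [AntState(ind, float(f)) for ind, f in zip(pop, fits)]


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    best_subset: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    pheromone_final: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    rule: str = "full_pseudo_random"

    @property
    def n_selected(self) -> int:
        return int(np.asarray(self.best_subset).sum())

    def selected_indices(self) -> list[int]:
        return np.flatnonzero(self.best_subset).tolist()

    def to_json(
        self, path: str | Path | None = None, feature_names: list[str] | None = None
    ) -> str:
        sel = self.selected_indices()
        payload = {
            "best_fitness": self.best_fitness,
            "n_selected": self.n_selected,
            "selected_indices": sel,
            "selected_features": [feature_names[i] for i in sel]
            if feature_names
            else None,
            "rule": self.rule,
            "history": self.history,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _better(cand: AntState, incumbent: AntState | None) -> bool:
    """Strictly better: higher fitness, then fewer features; the incumbent
    wins exact ties (first-found)."""
    if incumbent is None:
        return True
    if cand.fitness != incumbent.fitness:
        return cand.fitness > incumbent.fitness
    return cand.n_selected < incumbent.n_selected


def run(
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    heuristic: HeuristicVector | None = None,
    cfg: SearchConfig | None = None,
    rule: str = "full_pseudo_random",
    evaluator: Callable[[np.ndarray], float] | None = None,
    n_features: int | None = None,
) -> SearchResult:
    """Run the full GA-aided ant colony search.

    Each iteration: construct ``cfg.n_ants`` tours with local pheromone
    updates, score every tour by cross-validated MCC, evolve the colony
    with the GA, promote the best of {tours, GA output, incumbent} to
    global best (ties: fewer features, then first-found), and apply the
    global pheromone update on its path. The incumbent is retained across
    iterations, so the best fitness trace is non-decreasing.

    Either pass a dataset (X, y) — the evaluator defaults to stratified
    5-fold CV of a decision tree, and the heuristic to MDGI — or pass a
    custom ``evaluator`` plus ``n_features`` (with a ``heuristic``) for
    surrogate fitness functions.
    """
    cfg = cfg if cfg is not None else SearchConfig()
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")

    if evaluator is None:
        evaluator = cfg.fitness_evaluator
    if evaluator is None:
        if X is None or y is None:
            raise ValueError("need (X, y) or an explicit evaluator")
        evaluator = SubsetEvaluator(X, y, k=5, seed=cfg.seed)
    if heuristic is None:
        if X is None or y is None:
            raise ValueError("need (X, y) to compute the default MDGI heuristic")
        heuristic = mdgi(X, y, seed=derive_seed(cfg.seed, "heuristic"))
    if n_features is None:
        n_features = len(heuristic)
    if len(heuristic) != n_features:
        raise ValueError("heuristic length does not match feature count")

    rng = np.random.default_rng(derive_seed(cfg.seed, "acs", rule))
    graph = PheromoneGraph.from_config(heuristic, cfg)

    global_best: AntState | None = None
    history: list[dict] = []
    for it in range(cfg.n_iterations):
        colony = [
            construct_tour(graph, rule, rng, cfg.batched_local_updates)
            for _ in range(cfg.n_ants)
        ]
        for ant in colony:
            try:
                ant.fitness = _evaluate(ant, evaluator)
            except Exception as exc:  # annotate with iteration context
                raise RuntimeError(
                    f"fitness evaluation failed in iteration {it}"
                ) from exc
        evolved = ga_evolve(colony, cfg, evaluator, rng)
        for cand in list(colony) + evolved:
            if _better(cand, global_best):
                global_best = cand.copy()
        global_update(graph, global_best)
        history.append(
            {
                "iteration": it,
                "best_fitness": global_best.fitness,
                "mean_fitness": float(np.mean([a.fitness for a in colony])),
                "mean_n_selected": float(np.mean([a.n_selected for a in colony])),
            }
        )

    return SearchResult(
        best_subset=global_best.subset.copy(),
        best_fitness=float(global_best.fitness),
        history=history,
        pheromone_final=graph.tau.copy(),
        config=cfg.to_dict(),
        rule=rule,
    )
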
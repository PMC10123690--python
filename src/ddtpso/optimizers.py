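"""Continuous population-based optimizers.

Implements three minimizers over a bounded box:

* plain particle swarm optimization (PSO) with a linearly decaying inertia
  weight,
* dipper throated optimization (DTO), a two-phase swarm rule in which the
  worst fraction of the population "flies" (velocity-driven exploration
  toward the current leader and the global best) while the rest "swims"
  (direct contraction toward the leader), and
* the dynamic hybrid DDTPSO, which starts with DTO and swaps between the
  two update rules whenever the best-so-far fitness stagnates.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from :attr:`OptimizerConfig.seed`, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Strategy",
    "OptimizerConfig",
    "CandidateSolution",
    "Population",
    "StrategyState",
    "OptimizationResult",
    "ConfigurationError",
    "inertia_weight",
    "init_population",
    "pso_update",
    "dto_update",
    "choose_strategy",
    "optimize",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


class ConfigurationError(ValueError):
    """Raised when an optimizer or experiment configuration is invalid."""


class Strategy(str, Enum):
    DTO = "DTO"
    PSO = "PSO"

    def other(self) -> "Strategy":
        return Strategy.PSO if self is Strategy.DTO else Strategy.DTO


@dataclass
class OptimizerConfig:
    """Configuration shared by PSO, DTO and the dynamic hybrid.

    Parameters
    ----------
    n_agents:
        Population size (search agents / particles). Default 10.
    n_iterations:
        Number of update iterations. Default 80.
    bounds:
        Either a single ``(low, high)`` pair applied to every dimension or
        a sequence of per-dimension pairs.
    inertia_max, inertia_min:
        End points of the linearly decaying PSO inertia weight
        ``w(t) = inertia_max - (inertia_max - inertia_min) * t / n_iterations``.
    c1, c2:
        PSO cognitive and social acceleration constants.
    exploration_fraction:
        Fraction of the population (worst-ranked agents) that takes the
        exploratory "flying" DTO update; the remainder "swims" toward the
        current leader.
    swap_patience:
        Number of consecutive non-improving iterations tolerated before the
        dynamic controller swaps strategies.
    swap_tolerance:
        Minimum decrease of the best-so-far fitness that counts as an
        improvement.
    strategy:
        ``"dynamic"`` (the hybrid), or ``"pso"`` / ``"dto"`` to pin a single
        update rule (plain-PSO and plain-DTO baselines).
    seed:
        Seed for the run's random generator.
    """

    n_agents: int = 10
    n_iterations: int = 80
    bounds: tuple | Sequence = (0.0, 1.0)
    inertia_max: float = 0.9
    inertia_min: float = 0.6
    c1: float = 2.0
    c2: float = 2.0
    exploration_fraction: float = 0.7
    swap_patience: int = 5
    swap_tolerance: float = 1e-8
    strategy: str = "dynamic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigurationError("n_agents must be at least 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be at least 1")
        if not (self.inertia_min <= self.inertia_max):
            raise ConfigurationError("inertia_min must not exceed inertia_max")
        if not (0.0 < self.exploration_fraction <= 1.0):
            raise ConfigurationError("exploration_fraction must lie in (0, 1]")
        if self.strategy not in ("dynamic", "pso", "dto"):
            raise ConfigurationError(
                f"unknown strategy {self.strategy!r}; expected dynamic/pso/dto"
            )

    def resolve_bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (low, high) arrays of length ``dim``."""
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim == 1:
            if b.shape != (2,):
                raise ConfigurationError("bounds must be (low, high) or per-dim pairs")
            low = np.full(dim, b[0])
            high = np.full(dim, b[1])
        else:
            if b.shape != (dim, 2):
                raise ConfigurationError(
                    f"per-dimension bounds have shape {b.shape}, expected ({dim}, 2)"
                )
            low, high = b[:, 0].copy(), b[:, 1].copy()
        if not (np.all(np.isfinite(low)) and np.all(np.isfinite(high))):
            raise ConfigurationError("bounds must be finite")
        if np.any(low >= high):
            raise ConfigurationError("each lower bound must be below its upper bound")
        return low, high


@dataclass
class CandidateSolution:
    """A single search agent (read-only view onto the population arrays)."""

    position: np.ndarray
    velocity: np.ndarray
    fitness: float
    personal_best_position: np.ndarray
    personal_best_fitness: float


@dataclass
class Population:
    """Vectorized population state for one optimization run."""

    positions: np.ndarray  # (n_agents, dim)
    velocities: np.ndarray  # (n_agents, dim)
    fitness: np.ndarray  # (n_agents,)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    low: np.ndarray
    high: np.ndarray
    objective: Objective
    iteration: int = 0
    best_history: list[float] = field(default_factory=list)
    n_nonfinite: int = 0

    @property
    def agents(self) -> list[CandidateSolution]:
        return [
            CandidateSolution(
                position=self.positions[i],
                velocity=self.velocities[i],
                fitness=float(self.fitness[i]),
                personal_best_position=self.pbest_positions[i],
                personal_best_fitness=float(self.pbest_fitness[i]),
            )
            for i in range(self.positions.shape[0])
        ]

    @property
    def global_best(self) -> CandidateSolution:
        return CandidateSolution(
            position=self.gbest_position.copy(),
            velocity=np.zeros_like(self.gbest_position),
            fitness=self.gbest_fitness,
            personal_best_position=self.gbest_position.copy(),
            personal_best_fitness=self.gbest_fitness,
        )

    def evaluate(self, rows: np.ndarray | None = None) -> None:
        """(Re-)evaluate fitness for ``rows`` (default all) and refresh bests.

        Non-finite objective values are replaced by ``+inf`` so the agent
        keeps its previous personal best; occurrences are counted and logged.
        """
        idx = np.arange(self.positions.shape[0]) if rows is None else rows
        for i in idx:
            value = float(self.objective(self.positions[i]))
            if not math.isfinite(value):
                self.n_nonfinite += 1
                logger.debug("non-finite objective value at agent %d; treated as +inf", i)
                value = math.inf
            self.fitness[i] = value
        # neutral moves accepted: equal fitness updates the personal best
        # position so the swarm stays mobile on plateau regions (piecewise
        # constant objectives such as binarized wrapper fitness)
        improved = self.fitness <= self.pbest_fitness
        self.pbest_positions[improved] = self.positions[improved]
        self.pbest_fitness[improved] = self.fitness[improved]
        best = int(np.argmin(self.pbest_fitness))
        # strict comparison: first-found global best wins on ties
        if self.pbest_fitness[best] < self.gbest_fitness:
            self.gbest_fitness = float(self.pbest_fitness[best])
            self.gbest_position = self.pbest_positions[best].copy()


@dataclass
class StrategyState:
    """Bookkeeping for the dynamic strategy-swapping controller."""

    current_strategy: Strategy = Strategy.DTO
    stagnation_count: int = 0
    strategy_log: list[Strategy] = field(default_factory=list)
    last_best: float = math.inf


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    best_history: list[float]
    strategy_log: list[Strategy]
    n_nonfinite: int = 0

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "best_history": [float(v) for v in self.best_history],
            "strategy_log": [s.value for s in self.strategy_log],
            "n_nonfinite": self.n_nonfinite,
        }


def inertia_weight(t: int, config: OptimizerConfig) -> float:
    """Linearly decaying inertia ``w(t)`` from inertia_max down to inertia_min."""
    frac = t / config.n_iterations
    return config.inertia_max - (config.inertia_max - config.inertia_min) * frac


def init_population(
    config: OptimizerConfig,
    dim: int,
    objective: Objective,
    rng: np.random.Generator,
) -> Population:
    """Uniformly initialize agents inside the bounds with zero velocities."""
    if dim < 1:
        raise ConfigurationError("dim must be at least 1")
    low, high = config.resolve_bounds(dim)
    positions = rng.uniform(low, high, size=(config.n_agents, dim))
    pop = Population(
        positions=positions,
        velocities=np.zeros((config.n_agents, dim)),
        fitness=np.full(config.n_agents, math.inf),
        pbest_positions=positions.copy(),
        pbest_fitness=np.full(config.n_agents, math.inf),
        gbest_position=positions[0].copy(),
        gbest_fitness=math.inf,
        low=low,
        high=high,
        objective=objective,
    )
    pop.evaluate()
    return pop


def pso_update(pop: Population, config: OptimizerConfig, rng: np.random.Generator) -> Population:
    """One PSO iteration: inertia + cognitive + social velocity update, clipped move."""
    n, dim = pop.positions.shape
    w = inertia_weight(pop.iteration, config)
    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))
    pop.velocities = (
        w * pop.velocities
        + config.c1 * r1 * (pop.pbest_positions - pop.positions)
        + config.c2 * r2 * (pop.gbest_position - pop.positions)
    )
    pop.positions = np.clip(pop.positions + pop.velocities, pop.low, pop.high)
    pop.evaluate()
    return pop


def dto_update(pop: Population, config: OptimizerConfig, rng: np.random.Generator) -> Population:
    """One DTO iteration.

    Agents are ranked by current fitness. The worst
    ``ceil(exploration_fraction * n_agents)`` agents take the exploratory
    flying update

        v <- K3*v + K4*r1*(x_best - x) + K5*r2*(x_gbest - x);  x <- clip(x + v)

    while the remaining (best-ranked) agents take the exploitative swimming
    update

        x <- clip(x_best - K1*|K2*x_best - x|)

    with K1 = 2*u1*(1 - t/T) and K2..K5 = u2..u5, u_i ~ Uniform(0, 1) drawn
    independently per agent per iteration.
    """
    n, dim = pop.positions.shape
    order = np.argsort(pop.fitness, kind="stable")
    x_best = pop.positions[order[0]].copy()
    n_fly = math.ceil(config.exploration_fraction * n)
    flyers = order[n - n_fly:]
    swimmers = order[: n - n_fly]

    u = rng.random((n, 5))
    t_frac = pop.iteration / config.n_iterations
    k1 = 2.0 * u[:, 0] * (1.0 - t_frac)
    k2, k3, k4, k5 = u[:, 1], u[:, 2], u[:, 3], u[:, 4]
    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))

    if flyers.size:
        f = flyers
        pop.velocities[f] = (
            k3[f, None] * pop.velocities[f]
            + k4[f, None] * r1[f] * (x_best - pop.positions[f])
            + k5[f, None] * r2[f] * (pop.gbest_position - pop.positions[f])
        )
        pop.positions[f] = np.clip(pop.positions[f] + pop.velocities[f], pop.low, pop.high)
    if swimmers.size:
        s = swimmers
        pop.positions[s] = np.clip(
            x_best - k1[s, None] * np.abs(k2[s, None] * x_best - pop.positions[s]),
            pop.low,
            pop.high,
        )
    pop.evaluate()
    return pop


def choose_strategy(
    state: StrategyState, best_history: Sequence[float], config: OptimizerConfig
) -> Strategy:
    """Pick the update rule for the next iteration.

    Dynamic rule: start with DTO; when the best-so-far fitness has failed to
    improve by more than ``swap_tolerance`` for ``swap_patience`` consecutive
    iterations, switch to the other rule and reset the counter. With a pinned
    ``config.strategy`` the corresponding rule is always returned.
    """
    if config.strategy == "pso":
        chosen = Strategy.PSO
    elif config.strategy == "dto":
        chosen = Strategy.DTO
    else:
        if best_history:
            current = best_history[-1]
            if state.last_best - current > config.swap_tolerance:
                state.stagnation_count = 0
            else:
                state.stagnation_count += 1
            state.last_best = min(state.last_best, current)
            if state.stagnation_count >= config.swap_patience:
                state.current_strategy = state.current_strategy.other()
                state.stagnation_count = 0
        chosen = state.current_strategy
    state.strategy_log.append(chosen)
    return chosen


def optimize(
    objective: Objective,
    dim: int,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Run the configured optimizer for ``config.n_iterations`` iterations.

    Returns the best position/fitness found, the best-so-far history (one
    entry per iteration, non-increasing) and the per-iteration strategy log.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, dim, objective, rng)
    state = StrategyState(last_best=pop.gbest_fitness)
    for _ in range(config.n_iterations):
        strategy = choose_strategy(state, pop.best_history, config)
        if strategy is Strategy.PSO:
            pso_update(pop, config, rng)
        else:
            dto_update(pop, config, rng)
        pop.iteration += 1
        pop.best_history.append(pop.gbest_fitness)
    return OptimizationResult(
        best_position=pop.gbest_position.copy(),
        best_fitness=pop.gbest_fitness,
        best_history=list(pop.best_history),
        strategy_log=list(state.strategy_log),
        n_nonfinite=pop.n_nonfinite,
    )


def pso_baseline_config(config: OptimizerConfig) -> OptimizerConfig:
    """Plain-PSO baseline: same budget, strategy pinned to PSO."""
    return replace(config, strategy="pso")


def dto_baseline_config(config: OptimizerConfig) -> OptimizerConfig:
    """Plain-DTO baseline: same budget, strategy pinned to DTO."""
    return replace(config, strategy="dto")
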
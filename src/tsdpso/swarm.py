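"""Particle-swarm primitives and the standard PSO optimizer.

The swarm state is held in flat numpy arrays (one row per particle).  The
velocity rule is the canonical three-term update

    v' = w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)

with velocities clamped to ``[-v_max, v_max]`` and positions clamped into
the search box (a clamped coordinate has its velocity zeroed).  ``r1, r2``
are by default independent uniform draws per coordinate per particle per
iteration; a scalar-per-particle mode is available.

A per-iteration history of personal-best and global-best positions is kept
so that delayed-information variants can look up ``pbest[k - tau]`` and
``gbest[k - tau]``; lookups before iteration 0 clamp to the initial entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "SwarmConfig",
    "SwarmState",
    "SwarmHistory",
    "OptimizationResult",
    "EvaluationError",
    "initialize_swarm",
    "standard_velocity_update",
    "position_update",
    "optimize_standard_pso",
]


class EvaluationError(RuntimeError):
    """Raised when an objective returns a non-finite fitness."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """A box-constrained minimization problem."""

    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    evaluate: Callable[[np.ndarray], float]
    name: str = "objective"

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != (self.dimension,) or upper.shape != (self.dimension,):
            raise ValueError("bounds must have shape (dimension,)")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be elementwise below upper bounds")

    @classmethod
    def from_benchmark(
        cls, name: str, dimension: int, variant: str = "standard"
    ) -> "ObjectiveSpec":
        from . import benchmarks

        fn = benchmarks.get_benchmark(name)
        lower, upper = fn.bounds(dimension)
        if fn.name in ("ackley", "rosenbrock"):
            evaluate = lambda x: fn.evaluate(x, variant=variant)  # noqa: E731
        else:
            evaluate = fn.evaluate
        return cls(dimension, lower, upper, evaluate, name=fn.name)


@dataclass
class SwarmConfig:
    """Run settings shared by the standard and switching-delay optimizers.

    Defaults follow the common swarm configuration for SVM tuning runs:
    20 particles, 500 iterations, acceleration coefficients 2/2, initial
    inertia 0.9, speed cap 4 and convergence tolerance 1e-3.
    """

    swarm_size: int = 20
    max_iterations: int = 500
    c1: float = 2.0
    c2: float = 2.0
    inertia: float = 0.9
    v_max: float = 4.0
    convergence_tolerance: float = 1e-3
    seed: int = 0
    r_mode: str = "per_coordinate"  # "per_coordinate" | "scalar"

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.max_iterations < 1:
            raise ValueError("swarm_size and max_iterations must be positive")
        if self.c1 <= 0 or self.c2 <= 0 or self.v_max <= 0:
            raise ValueError("c1, c2 and v_max must be positive")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.r_mode not in ("scalar", "per_coordinate"):
            raise ValueError("r_mode must be 'scalar' or 'per_coordinate'")


class SwarmHistory:
    """Ring-free per-iteration store of pbest/gbest positions.

    Entry ``k`` is the state after the pbest/gbest update of iteration
    ``k`` (entry 0 is the initialization).  Lookups clamp negative indices
    to 0 so that delayed reads are total.
    """

    def __init__(self) -> None:
        self._pbest: list[np.ndarray] = []
        self._gbest: list[np.ndarray] = []

    def append(self, pbest_positions: np.ndarray, gbest_position: np.ndarray) -> None:
        self._pbest.append(pbest_positions.copy())
        self._gbest.append(gbest_position.copy())

    def __len__(self) -> int:
        return len(self._pbest)

    def pbest_at(self, k: int) -> np.ndarray:
        return self._pbest[max(k, 0)]

    def gbest_at(self, k: int) -> np.ndarray:
        return self._gbest[max(k, 0)]


@dataclass
class SwarmState:
    """Mutable swarm: positions, velocities and best-so-far bookkeeping."""

    positions: np.ndarray  # (s, D)
    velocities: np.ndarray  # (s, D)
    fitness: np.ndarray  # (s,)
    pbest_positions: np.ndarray  # (s, D)
    pbest_fitness: np.ndarray  # (s,)
    stall_counts: np.ndarray  # (s,) iterations since pbest improved
    gbest_index: int
    history: SwarmHistory = field(default_factory=SwarmHistory)

    @property
    def gbest_position(self) -> np.ndarray:
        return self.pbest_positions[self.gbest_index]

    @property
    def gbest_fitness(self) -> float:
        return float(self.pbest_fitness[self.gbest_index])


@dataclass
class OptimizationResult:
    gbest_position: np.ndarray
    gbest_fitness: float
    convergence_curve: np.ndarray  # best fitness after each iteration
    iterations_used: int
    state_trace: np.ndarray  # evolutionary states (empty for standard PSO)


def _evaluate_all(
    objective: ObjectiveSpec, positions: np.ndarray, iteration: int
) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        f = float(objective.evaluate(x))
        if not np.isfinite(f):
            raise EvaluationError(
                f"objective returned non-finite fitness {f!r} for particle "
                f"{i} at iteration {iteration}"
            )
        out[i] = f
    return out


def initialize_swarm(
    objective: ObjectiveSpec, config: SwarmConfig, rng: np.random.Generator
) -> SwarmState:
    """Uniform positions in the box, uniform velocities in ±v_max."""
    s, d = config.swarm_size, objective.dimension
    span = objective.upper - objective.lower
    positions = objective.lower + rng.random((s, d)) * span
    velocities = rng.uniform(-config.v_max, config.v_max, (s, d))
    fitness = _evaluate_all(objective, positions, iteration=0)
    state = SwarmState(
        positions=positions,
        velocities=velocities,
        fitness=fitness,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        stall_counts=np.zeros(s, dtype=int),
        gbest_index=int(np.argmin(fitness)),
    )
    state.history.append(state.pbest_positions, state.gbest_position)
    return state


def standard_velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
    v_max: float,
) -> np.ndarray:
    """Three-term velocity rule, clamped to ±v_max."""
    velocity = np.asarray(velocity, dtype=float)
    for other in (position, pbest):
        if np.shape(other) != velocity.shape:
            raise ValueError("velocity/position/pbest shapes must agree")
    if np.shape(gbest)[-1] != velocity.shape[-1]:
        raise ValueError("gbest dimension must match velocity")
    v_new = (
        omega * velocity
        + c1 * np.asarray(r1) * (pbest - position)
        + c2 * np.asarray(r2) * (gbest - position)
    )
    return np.clip(v_new, -v_max, v_max)


def position_update(
    position: np.ndarray,
    velocity: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """x' = x + v clamped into the box; clamped coordinates zero velocity.

    Returns the new position and the (possibly zeroed) velocity.
    """
    position = np.asarray(position, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if position.shape != velocity.shape:
        raise ValueError("position and velocity shapes must agree")
    raw = position + velocity
    clamped = np.clip(raw, lower, upper)
    velocity = np.where(raw == clamped, velocity, 0.0)
    return clamped, velocity


def _draw_r(rng: np.random.Generator, config: SwarmConfig, d: int) -> np.ndarray:
    if config.r_mode == "scalar":
        return rng.random((config.swarm_size, 1))
    return rng.random((config.swarm_size, d))


def _update_bests(state: SwarmState) -> None:
    improved = state.fitness < state.pbest_fitness
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitness[improved] = state.fitness[improved]
    state.stall_counts[improved] = 0
    state.stall_counts[~improved] += 1
    state.gbest_index = int(np.argmin(state.pbest_fitness))


def optimize_standard_pso(
    objective: ObjectiveSpec, config: SwarmConfig
) -> OptimizationResult:
    """Run standard PSO until the tolerance or the iteration budget."""
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(objective, config, rng)
    curve = [state.gbest_fitness]
    iterations = 0
    for k in range(1, config.max_iterations + 1):
        if state.gbest_fitness <= config.convergence_tolerance:
            break
        r1 = _draw_r(rng, config, objective.dimension)
        r2 = _draw_r(rng, config, objective.dimension)
        state.velocities = standard_velocity_update(
            state.velocities,
            state.positions,
            state.pbest_positions,
            state.gbest_position[None, :],
            config.inertia,
            config.c1,
            config.c2,
            r1,
            r2,
            config.v_max,
        )
        state.positions, state.velocities = position_update(
            state.positions, state.velocities, objective.lower, objective.upper
        )
        state.fitness = _evaluate_all(objective, state.positions, k)
        _update_bests(state)
        state.history.append(state.pbest_positions, state.gbest_position)
        curve.append(state.gbest_fitness)
        iterations = k
    return OptimizationResult(
        gbest_position=state.gbest_position.copy(),
        gbest_fitness=state.gbest_fitness,
        convergence_curve=np.asarray(curve),
        iterations_used=iterations,
        state_trace=np.empty(0, dtype=int),
    )
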
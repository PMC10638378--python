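"""Traction switching-delay particle swarm optimization (TSDPSO).

TSDPSO augments standard PSO with four coupled mechanisms:

* **Evolutionary-state estimation.**  From the mean inter-particle
  distances ``d_i`` the evolution factor
  ``E_f = (d_g - d_min) / (d_max - d_min)`` locates the swarm on a
  convergence/exploration/development/jump-out axis (states 1-4).
* **Markov state switching.**  The state proposed by ``E_f`` is passed
  through a tridiagonal transition matrix with persistence ``x`` on the
  diagonal, adding stochastic inertia between adjacent states.  A
  deterministic mode (pure threshold classification) is also provided.
* **State-dependent parameters and delays.**  Acceleration coefficients
  follow the per-state schedule (2/2, 2.1/1.9, 2.2/1.8, 1.8/2.2), the
  inertia weight tracks the evolution factor as ``w = 0.5 E_f + 0.4``,
  and the velocity update reads personal/global bests delayed by
  state-dependent lags ``tau1, tau2 <= tau_max``.
* **Traction.**  A particle whose personal best has stalled for
  ``stall_threshold`` iterations receives an additive velocity pull
  toward the (delayed) global best, scaled by the fitness-based traction
  factor ``(f_i - f_min) / (f_avg - f_min)``.

With delays and traction disabled, the state fixed to 1 and the inertia
frozen, the loop reduces exactly (bitwise, under a shared seed) to
standard PSO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .swarm import (
    ObjectiveSpec,
    OptimizationResult,
    SwarmConfig,
    _draw_r,
    _evaluate_all,
    _update_bests,
    initialize_swarm,
    position_update,
)

__all__ = [
    "CONVERGENCE",
    "EXPLORATION",
    "DEVELOPMENT",
    "JUMP_OUT",
    "DelayPolicy",
    "TractionConfig",
    "transition_matrix",
    "mean_particle_distance",
    "evolution_factor",
    "classify_state",
    "next_state",
    "inertia_weight",
    "state_parameters",
    "select_delays",
    "traction_term",
    "tsdpso_velocity_update",
    "optimize_tsdpso",
]

# Evolutionary states of the swarm
CONVERGENCE, EXPLORATION, DEVELOPMENT, JUMP_OUT = 1, 2, 3, 4

# Per-state acceleration coefficients (c1, c2)
_STATE_PARAMS: dict[int, tuple[float, float]] = {
    CONVERGENCE: (2.0, 2.0),
    EXPLORATION: (2.1, 1.9),
    DEVELOPMENT: (2.2, 1.8),
    JUMP_OUT: (1.8, 2.2),
}


@dataclass
class DelayPolicy:
    """How far back delayed pbest/gbest reads may reach, per state.

    ``tau_max`` caps every lag.  The per-state rule: convergence uses the
    current bests (0, 0); exploration delays gbest only; development
    delays pbest only; jump-out delays both, each drawn uniformly from
    ``{1..min(k, tau_max)}``.
    """

    tau_max: int = 10

    def __post_init__(self) -> None:
        if self.tau_max < 0:
            raise ValueError("tau_max must be non-negative")


@dataclass
class TractionConfig:
    """Trigger for the traction pull on long-stalled particles."""

    stall_threshold: int = 10
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.stall_threshold < 1:
            raise ValueError("stall_threshold must be >= 1")


def transition_matrix(x: float) -> np.ndarray:
    """Tridiagonal 4x4 state-transition matrix with persistence ``x``.

    Row i keeps the current state with probability ``x`` and spreads the
    remaining mass over adjacent states (edge states have one neighbor).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("persistence x must be in [0, 1]")
    h = (1.0 - x) / 2.0
    return np.array(
        [
            [x, 1.0 - x, 0.0, 0.0],
            [h, x, h, 0.0],
            [0.0, h, x, h],
            [0.0, 0.0, 1.0 - x, x],
        ]
    )


def mean_particle_distance(positions: np.ndarray, i: int | None = None) -> np.ndarray | float:
    """Mean Euclidean distance from each particle to all particles.

    The self-distance (zero) is included in the mean, so the divisor is
    the swarm size.  With ``i`` given, returns the scalar ``d_i``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 1:
        raise ValueError("positions must be a non-empty (s, D) array")
    diff = positions[:, None, :] - positions[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2)).mean(axis=1)
    if i is None:
        return d
    if not 0 <= i < positions.shape[0]:
        raise IndexError(f"particle index {i} out of range")
    return float(d[i])


def evolution_factor(d_g: float, d_min: float, d_max: float) -> float:
    """Normalized position of the best particle's mean distance."""
    if not (d_min <= d_g <= d_max):
        raise ValueError("d_g must lie in [d_min, d_max]")
    if d_max == d_min:
        return 0.0  # fully collapsed swarm: treat as deep convergence
    return (d_g - d_min) / (d_max - d_min)


def classify_state(e_f: float) -> int:
    """Threshold classification of the evolution factor into states 1-4."""
    if not 0.0 <= e_f <= 1.0:
        raise ValueError("evolution factor must be in [0, 1]")
    if e_f <= 0.25:
        return CONVERGENCE
    if e_f <= 0.5:
        return EXPLORATION
    if e_f <= 0.75:
        return DEVELOPMENT
    return JUMP_OUT


def next_state(
    current: int,
    proposed: int,
    matrix: np.ndarray,
    draw: float | None = None,
    mode: str = "markov",
) -> int:
    """Resolve the next evolutionary state.

    In ``markov`` mode the state is sampled from the transition-matrix
    row of the proposal, so the chain may persist in an adjacent state;
    ``draw`` is a uniform [0,1) variate.  In ``deterministic`` mode the
    proposal is returned unchanged.
    """
    if proposed not in _STATE_PARAMS or current not in _STATE_PARAMS:
        raise ValueError("states must be in {1, 2, 3, 4}")
    if mode == "deterministic":
        return proposed
    if mode != "markov":
        raise ValueError("mode must be 'markov' or 'deterministic'")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4) or np.any(matrix < 0) or np.any(matrix > 1):
        raise ValueError("transition matrix must be 4x4 with entries in [0,1]")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    if draw is None:
        raise ValueError("markov mode requires a uniform draw")
    row = matrix[proposed - 1]
    return int(np.searchsorted(np.cumsum(row), draw, side="right")) + 1


def inertia_weight(e_f: float) -> float:
    """Linear inertia schedule ``w = 0.5 E_f + 0.4`` on [0.4, 0.9]."""
    if not 0.0 <= e_f <= 1.0:
        raise ValueError("evolution factor must be in [0, 1]")
    return 0.5 * e_f + 0.4


def state_parameters(state: int) -> tuple[float, float]:
    """Acceleration coefficients (c1, c2) for an evolutionary state."""
    try:
        return _STATE_PARAMS[state]
    except KeyError:
        raise ValueError(f"invalid evolutionary state {state}") from None


def select_delays(
    state: int, k: int, policy: DelayPolicy, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw the (tau1, tau2) lags for iteration ``k`` in a given state."""
    if k < 0:
        raise ValueError("iteration index must be non-negative")
    m = min(k, policy.tau_max)
    if m == 0 or state == CONVERGENCE:
        return 0, 0
    if state == EXPLORATION:
        return 0, int(rng.integers(1, m + 1))
    if state == DEVELOPMENT:
        return int(rng.integers(1, m + 1)), 0
    if state == JUMP_OUT:
        return int(rng.integers(1, m + 1)), int(rng.integers(1, m + 1))
    raise ValueError(f"invalid evolutionary state {state}")


def traction_term(
    f_i: float,
    f_min: float,
    f_avg: float,
    gbest_delayed: np.ndarray,
    pbest_delayed: np.ndarray,
    rand_draw: float,
) -> np.ndarray:
    """Additive pull toward the delayed global best for a stalled particle.

    The traction factor ``(f_i - f_min)/(f_avg - f_min)`` weights poorly
    performing particles more strongly; a fully converged swarm
    (``f_avg == f_min``) yields zero traction.
    """
    gbest_delayed = np.asarray(gbest_delayed, dtype=float)
    pbest_delayed = np.asarray(pbest_delayed, dtype=float)
    if gbest_delayed.shape != pbest_delayed.shape:
        raise ValueError("delayed gbest/pbest shapes must agree")
    if f_avg == f_min:
        return np.zeros_like(gbest_delayed)
    factor = (f_i - f_min) / (f_avg - f_min)
    return factor * rand_draw * (gbest_delayed - pbest_delayed)


def tsdpso_velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest_delayed: np.ndarray,
    gbest_delayed: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
    v_max: float,
    traction: np.ndarray | None = None,
) -> np.ndarray:
    """Delayed three-term velocity rule plus optional traction, clamped."""
    velocity = np.asarray(velocity, dtype=float)
    v_new = (
        omega * velocity
        + c1 * np.asarray(r1) * (pbest_delayed - position)
        + c2 * np.asarray(r2) * (gbest_delayed - position)
    )
    if traction is not None:
        v_new = v_new + traction
    return np.clip(v_new, -v_max, v_max)


def optimize_tsdpso(
    objective: ObjectiveSpec,
    config: SwarmConfig,
    delay_policy: DelayPolicy | None = None,
    traction: TractionConfig | None = None,
    transition_x: float = 0.6,
    state_mode: str = "markov",
    fixed_state: int | None = None,
    freeze_inertia: bool = False,
) -> OptimizationResult:
    """Run the full TSDPSO loop.

    Per iteration: evaluate -> update bests/stall counters -> compute the
    evolution factor -> adapt the inertia weight -> classify and switch
    the evolutionary state -> pick per-state coefficients and delays ->
    velocity update with traction for stalled particles -> position
    update.  Stops when the global best reaches the tolerance or the
    budget is spent.  Fully reproducible from ``config.seed``.

    ``fixed_state`` pins the evolutionary state (bypassing estimation);
    ``freeze_inertia`` keeps ``config.inertia`` instead of the adaptive
    schedule.  Together with ``DelayPolicy(tau_max=0)`` and traction
    disabled these options reduce the loop to standard PSO.
    """
    delay_policy = delay_policy or DelayPolicy()
    traction = traction or TractionConfig()
    matrix = transition_matrix(transition_x)
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(objective, config, rng)
    curve = [state.gbest_fitness]
    chain_state = fixed_state if fixed_state is not None else CONVERGENCE
    trace = []
    iterations = 0
    for k in range(1, config.max_iterations + 1):
        if state.gbest_fitness <= config.convergence_tolerance:
            break
        # State estimation from the current particle cloud (no RNG).
        d = mean_particle_distance(state.positions)
        e_f = evolution_factor(
            float(d[state.gbest_index]), float(d.min()), float(d.max())
        )
        omega = config.inertia if freeze_inertia else inertia_weight(e_f)
        if fixed_state is not None:
            chain_state = fixed_state
        else:
            proposed = classify_state(e_f)
            if state_mode == "markov":
                chain_state = next_state(
                    chain_state, proposed, matrix, float(rng.random()), "markov"
                )
            else:
                chain_state = next_state(chain_state, proposed, matrix, None, state_mode)
        trace.append(chain_state)
        c1, c2 = state_parameters(chain_state)
        hist_k = len(state.history) - 1
        tau1, tau2 = select_delays(chain_state, hist_k, delay_policy, rng)
        pbest_del = state.history.pbest_at(hist_k - tau1)
        gbest_del = state.history.gbest_at(hist_k - tau2)
        r1 = _draw_r(rng, config, objective.dimension)
        r2 = _draw_r(rng, config, objective.dimension)
        po: np.ndarray | None = None
        if traction.enabled:
            trapped = state.stall_counts >= traction.stall_threshold
            if np.any(trapped):
                po = np.zeros_like(state.positions)
                f_min = float(state.fitness.min())
                f_avg = float(state.fitness.mean())
                gbest_tr = state.history.gbest_at(hist_k - tau1)
                draws = rng.random(int(trapped.sum()))
                for draw, i in zip(draws, np.flatnonzero(trapped)):
                    po[i] = traction_term(
                        float(state.fitness[i]),
                        f_min,
                        f_avg,
                        gbest_tr,
                        pbest_del[i],
                        float(draw),
                    )
        state.velocities = tsdpso_velocity_update(
            state.velocities,
            state.positions,
            pbest_del,
            gbest_del[None, :],
            omega,
            c1,
            c2,
            r1,
            r2,
            config.v_max,
            traction=po,
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
        state_trace=np.asarray(trace, dtype=int),
    )
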
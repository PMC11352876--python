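"""Population metaheuristics and the hyperparameter search-space codec.

Two optimizers are provided, both minimizing:

* particle swarm optimization with inertia/cognitive/social velocity
  updates, bound clipping, and per-dimension velocity clamping;
* a parrot-flock optimizer whose agents each perform one of four behaviors
  per iteration (foraging, staying, communicating, fear of strangers),
  with Lévy-flight steps and greedy acceptance.

Random draws are injectable so single-step hand cases are exactly testable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Bounds",
    "Particle",
    "SwarmState",
    "ParrotState",
    "OptimResult",
    "pso_init",
    "pso_step",
    "pso_optimize",
    "levy_flight",
    "po_init",
    "po_step",
    "po_optimize",
    "SearchSpace",
    "default_search_space",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]

#: Velocity clamp as a fraction of each dimension's bound range.
VELOCITY_CLAMP_FRAC = 0.2


@dataclass
class Bounds:
    """Per-dimension box constraints with ``lb < ub`` elementwise."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape:
            raise ConfigurationError("lb and ub must have matching shapes")
        if not np.all(self.lb < self.ub):
            raise ConfigurationError("need lb < ub elementwise")

    @property
    def dim(self) -> int:
        return int(self.lb.size)

    @property
    def range(self) -> np.ndarray:
        return self.ub - self.lb

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lb + rng.random((n, self.dim)) * self.range


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_value: float = math.inf


@dataclass
class SwarmState:
    particles: list[Particle]
    bounds: Bounds
    best_position: np.ndarray
    best_value: float
    t: int
    inertia: float
    c1: float
    c2: float
    rng: np.random.Generator
    evaluations: int = 0


@dataclass
class ParrotState:
    positions: np.ndarray  # (n_agents, dim)
    values: np.ndarray  # current objective value per agent
    bounds: Bounds
    best_position: np.ndarray
    best_value: float
    t: int
    max_iter: int
    rng: np.random.Generator
    evaluations: int = 0

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class OptimResult:
    """Best solution found plus the best-so-far trajectory."""

    best_position: np.ndarray
    best_value: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0


def _safe_eval(objective: Objective, x: np.ndarray) -> float:
    value = float(objective(x))
    if not math.isfinite(value):
        warnings.warn(f"objective returned non-finite value at {x!r}; treated as +inf",
                      RuntimeWarning, stacklevel=3)
        return math.inf
    return value


def pso_init(
    bounds: Bounds,
    n: int,
    seed: int | None = None,
    objective: Objective | None = None,
    inertia: float = 0.9,
    c1: float = 2.0,
    c2: float = 2.0,
) -> SwarmState:
    """Create a swarm: positions uniform within bounds, velocities zero,
    personal bests at the initial positions.

    When ``objective`` is given each initial position is evaluated and the
    global best is the best initial particle; otherwise all best values
    start at +inf and the global best is set on the first step.
    """
    if n < 1:
        raise ConfigurationError("swarm size must be >= 1")
    rng = np.random.default_rng(seed)
    positions = bounds.sample(rng, n)
    particles = []
    evaluations = 0
    for i in range(n):
        value = math.inf
        if objective is not None:
            value = _safe_eval(objective, positions[i])
            evaluations += 1
        particles.append(
            Particle(positions[i].copy(), np.zeros(bounds.dim), positions[i].copy(), value)
        )
    best = min(particles, key=lambda p: p.best_value)
    return SwarmState(
        particles=particles,
        bounds=bounds,
        best_position=best.best_position.copy(),
        best_value=best.best_value,
        t=0,
        inertia=inertia,
        c1=c1,
        c2=c2,
        rng=rng,
        evaluations=evaluations,
    )


def pso_step(
    state: SwarmState,
    objective: Objective,
    rand_pair: tuple[float, float] | None = None,
) -> SwarmState:
    """Advance the swarm one iteration in place (and return it).

    Per particle, with fresh uniform draws r1, r2 (or the injected
    ``rand_pair``):

        v <- inertia * v + c1 * r1 * (p_best - x) + c2 * r2 * (g_best - x)
        x <- x + v

    Velocities are clamped to 20% of each dimension's range and positions
    are clipped to the bounds before evaluation; personal and global bests
    are then updated and the iteration counter advances.
    """
    vmax = VELOCITY_CLAMP_FRAC * state.bounds.range
    for particle in state.particles:
        if rand_pair is None:
            r1 = state.rng.random()
            r2 = state.rng.random()
        else:
            r1, r2 = rand_pair
        velocity = (
            state.inertia * particle.velocity
            + state.c1 * r1 * (particle.best_position - particle.position)
            + state.c2 * r2 * (state.best_position - particle.position)
        )
        velocity = np.clip(velocity, -vmax, vmax)
        position = state.bounds.clip(particle.position + velocity)
        particle.velocity = velocity
        particle.position = position
        value = _safe_eval(objective, position)
        state.evaluations += 1
        if value < particle.best_value:
            particle.best_value = value
            particle.best_position = position.copy()
            if value < state.best_value:
                state.best_value = value
                state.best_position = position.copy()
    state.t += 1
    return state


def pso_optimize(
    objective: Objective,
    bounds: Bounds,
    n: int = 9,
    max_iter: int = 100,
    seed: int | None = None,
    inertia: float = 0.9,
    c1: float = 2.0,
    c2: float = 2.0,
) -> OptimResult:
    """Run PSO for ``max_iter`` iterations and return the best solution.

    The history holds the best-so-far value after initialization and after
    each iteration (``max_iter + 1`` entries, non-increasing); total
    objective evaluations equal ``n * (max_iter + 1)`` exactly.
    """
    if max_iter < 1:
        raise ConfigurationError("max_iter must be >= 1")
    state = pso_init(bounds, n, seed, objective, inertia, c1, c2)
    history = [state.best_value]
    for _ in range(max_iter):
        pso_step(state, objective)
        history.append(state.best_value)
        logger.debug("pso iter=%d best=%.6g evals=%d", state.t, state.best_value,
                     state.evaluations)
    return OptimResult(state.best_position.copy(), state.best_value, history,
                       state.evaluations)


def levy_flight(
    dim: int, beta: float = 1.5, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Heavy-tailed step vector via the Mantegna algorithm.

    Each component is ``u / |v|**(1/beta)`` with ``u ~ N(0, sigma^2)`` and
    ``v ~ N(0, 1)``, where sigma is the Mantegna scale for stability index
    ``beta`` in (1, 2].
    """
    if dim < 1:
        raise ConfigurationError("dim must be >= 1")
    if not (1 < beta <= 2):
        raise ConfigurationError(f"beta must lie in (1, 2], got {beta}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = (
        math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    return u / np.abs(v) ** (1 / beta)


def po_init(
    bounds: Bounds,
    n_agents: int,
    max_iter: int,
    seed: int | None = None,
    objective: Objective | None = None,
) -> ParrotState:
    """Initialize the flock uniformly within bounds: lb + rand * (ub - lb)."""
    if n_agents < 2:
        raise ConfigurationError("po requires at least 2 agents (population mean)")
    if max_iter < 1:
        raise ConfigurationError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    positions = bounds.sample(rng, n_agents)
    evaluations = 0
    if objective is not None:
        values = np.array([_safe_eval(objective, x) for x in positions])
        evaluations = n_agents
    else:
        values = np.full(n_agents, math.inf)
    best_idx = int(np.argmin(values))
    return ParrotState(
        positions=positions,
        values=values,
        bounds=bounds,
        best_position=positions[best_idx].copy(),
        best_value=float(values[best_idx]),
        t=0,
        max_iter=max_iter,
        rng=rng,
        evaluations=evaluations,
    )


BEHAVIORS = ("foraging", "staying", "communicating", "fear")


def _po_candidate(
    y: np.ndarray,
    state: ParrotState,
    behavior: str,
    rand: Callable[[], float],
    levy: Callable[[int], np.ndarray],
    p_draw: Callable[[], float],
) -> np.ndarray:
    """One behavior update as printed, before bound clipping.

    ``rand`` is called fresh for every occurrence of rand(0,1) in the
    corresponding equation.
    """
    t, max_iter = state.t, state.max_iter
    dim = y.size
    y_best = state.best_position
    y_mean = state.mean_position
    frac = t / max_iter
    if behavior == "foraging":
        return (y - y_best) * levy(dim) + rand() * (1 - frac) ** (2 * frac) * y_mean
    if behavior == "staying":
        return y + y_best * levy(dim) + rand() * np.ones(dim)
    if behavior == "communicating":
        if p_draw() <= 0.5:
            return 0.2 * rand() * (1 - frac) * (y - y_mean)
        return np.full(dim, 0.2 * rand() * math.exp(-t / (rand() * max_iter + 1e-300)))
    if behavior == "fear":
        return (
            y
            + rand() * math.cos(0.5 * math.pi * frac) * (y_best - y)
            - math.cos(rand() * math.pi) * frac ** (2 / max_iter) * (y - y_best)
        )
    raise ConfigurationError(f"unknown behavior {behavior!r}")


def po_step(
    state: ParrotState,
    objective: Objective,
    behavior_override: str | None = None,
    rand_fn: Callable[[], float] | None = None,
    levy_fn: Callable[[int], np.ndarray] | None = None,
    p_fn: Callable[[], float] | None = None,
) -> ParrotState:
    """Advance the flock one iteration in place (and return it).

    Each agent selects one of the four behaviors uniformly at random (or
    ``behavior_override``), produces a candidate position from the printed
    equation, clips it to the bounds, and keeps it only if the objective
    improves (greedy acceptance).  ``rand_fn`` / ``levy_fn`` / ``p_fn``
    stub the corresponding random draws for hand-checkable single steps.
    """
    if state.t >= state.max_iter:
        raise ConfigurationError("po_step called past max_iter")
    rng = state.rng
    rand = rand_fn if rand_fn is not None else (lambda: float(rng.random()))
    levy = levy_fn if levy_fn is not None else (lambda d: levy_flight(d, rng=rng))
    p_draw = p_fn if p_fn is not None else (lambda: float(rng.random()))
    for i in range(state.positions.shape[0]):
        behavior = behavior_override or BEHAVIORS[int(rng.integers(len(BEHAVIORS)))]
        candidate = _po_candidate(state.positions[i], state, behavior, rand, levy, p_draw)
        candidate = state.bounds.clip(candidate)
        value = _safe_eval(objective, candidate)
        state.evaluations += 1
        if value < state.values[i]:
            state.positions[i] = candidate
            state.values[i] = value
            if value < state.best_value:
                state.best_value = value
                state.best_position = candidate.copy()
    state.t += 1
    return state


def po_optimize(
    objective: Objective,
    bounds: Bounds,
    n_agents: int = 30,
    max_iter: int = 1000,
    seed: int | None = None,
) -> OptimResult:
    """Run the parrot optimizer and return the best solution found.

    History holds ``max_iter + 1`` best-so-far values (non-increasing under
    greedy acceptance); evaluations equal ``n_agents * (max_iter + 1)``.
    """
    state = po_init(bounds, n_agents, max_iter, seed, objective)
    history = [state.best_value]
    for _ in range(max_iter):
        po_step(state, objective)
        history.append(state.best_value)
        if state.t % 100 == 0:
            logger.debug("po iter=%d best=%.6g evals=%d", state.t, state.best_value,
                         state.evaluations)
    return OptimResult(state.best_position.copy(), state.best_value, history,
                       state.evaluations)


# ---------------------------------------------------------------------------
# Hyperparameter search-space codec
# ---------------------------------------------------------------------------


@dataclass
class SearchSpace:
    """Maps optimizer coordinates on the unit cube to classifier settings.

    Dimension 0: learning rate, log-uniform over [lr_low, lr_high].
    Dimension 1: hidden units, rounded onto [units_low, units_high].
    Dimension 2: dropout, affine onto [dropout_low, dropout_high].
    Out-of-bounds coordinates are clipped before decoding.
    """

    lr_low: float = 1e-5
    lr_high: float = 1e-2
    units_low: int = 16
    units_high: int = 128
    dropout_low: float = 0.1
    dropout_high: float = 0.7

    @property
    def dim(self) -> int:
        return 3

    def bounds(self) -> Bounds:
        return Bounds(np.zeros(3), np.ones(3))

    def decode(self, position: Sequence[float] | np.ndarray) -> dict:
        position = np.asarray(position, dtype=float)
        if position.shape != (self.dim,):
            raise ConfigurationError(
                f"position must have dimension {self.dim}, got shape {position.shape}"
            )
        u = np.clip(position, 0.0, 1.0)
        log_lo, log_hi = math.log10(self.lr_low), math.log10(self.lr_high)
        lr = float(10.0 ** (log_lo + u[0] * (log_hi - log_lo)))
        units = int(round(self.units_low + u[1] * (self.units_high - self.units_low)))
        dropout = float(self.dropout_low + u[2] * (self.dropout_high - self.dropout_low))
        return {"learning_rate": lr, "hidden_units": units, "dropout": dropout}

    def encode(self, config: dict) -> np.ndarray:
        log_lo, log_hi = math.log10(self.lr_low), math.log10(self.lr_high)
        u0 = (math.log10(config["learning_rate"]) - log_lo) / (log_hi - log_lo)
        u1 = (config["hidden_units"] - self.units_low) / (self.units_high - self.units_low)
        u2 = (config["dropout"] - self.dropout_low) / (self.dropout_high - self.dropout_low)
        return np.clip(np.array([u0, u1, u2]), 0.0, 1.0)


def default_search_space() -> SearchSpace:
    return SearchSpace()
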
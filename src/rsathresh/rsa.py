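"""Reptile Search Algorithm with a global-best (Gbest) velocity operator.

The optimizer searches the continuous box ``[LB, UB]^n`` (for thresholding,
``LB = 1``, ``UB = L−1 = 255`` and ``n`` is the threshold count) for the
vector maximizing a threshold objective.  One run of ``T`` iterations moves
through four phases in equal quarters, mimicking crocodile behaviour:

1. *High walk* (t ≤ T/4, exploration):
   ``x' = best_j·η_ij·β − R_ij·rand``
2. *Belly walk* (T/4 < t ≤ T/2, exploration):
   ``x' = best_j·x_{r1,j}·ES(t)·rand``
3. *Hunting coordination* (T/2 < t ≤ 3T/4, exploitation):
   ``x' = best_j·P_ij·rand``
4. *Hunting cooperation* (3T/4 < t ≤ T, exploitation):
   ``x' = best_j − η_ij·ε − R_ij·rand``

with hunting operator ``η_ij = best_j·P_ij``, percentage difference
``P_ij = α + (x_ij − mean(x_i)) / (best_j·(UB−LB) + ε)``, reduction
``R_ij = (best_j − x_{r2,j}) / (best_j + ε)`` and evolutionary sense
``ES(t) = 2·r3·(1 − t/T)`` shrinking from magnitude 2 toward 0.

After the phase move, every candidate also takes a PSO-style step toward
the population's global best::

    v' = w·v + c1·rand1·(Pbest − x) + c2·rand2·(Gbest − x);  x' = x + v'

with inertia ``w`` decayed linearly from ``w_max`` to ``w_min``.  Selection
is greedy: the better of {old position, phase move, Gbest move} is kept, so
the best-so-far fitness trace is monotone non-decreasing (elitism).

Fitness is always evaluated on *decoded* thresholds: the continuous
position is clamped, rounded half-up, sorted, and de-duplicated to a valid
strictly increasing integer vector; the search itself stays continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .histograms import N_LEVELS, ChannelHistogram
from .objectives import ObjectiveEvaluator, ThresholdVector

PHASES = ("high_walk", "belly_walk", "hunt_coordination", "hunt_cooperation")


@dataclass(frozen=True)
class SearchBounds:
    """Box bounds of the continuous search space."""

    lower: float = 1.0
    upper: float = float(N_LEVELS - 1)
    dimension: int = 1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.dimension < 1:
            raise ValueError("dimension must be ≥ 1")


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunables of the RSA-Gbest optimizer.

    Defaults follow the study protocol: population 25, 100 iterations,
    β = α = 0.1 for the walk/hunt strategies, and the Gbest operator's
    inertia decayed linearly from 0.9 to 0.2 with c1 = c2 = 2.
    """

    population: int = 25
    iterations: int = 100
    beta: float = 0.1
    alpha: float = 0.1
    epsilon: float = 1e-10
    w_max: float = 0.9
    w_min: float = 0.2
    c1: float = 2.0
    c2: float = 2.0
    seed: int | None = None
    runs: int = 30

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be ≥ 2")
        if self.iterations < 4:
            raise ValueError("need ≥ 4 iterations (phase quarters must be non-empty)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class Population:
    """Position matrix X plus the per-candidate Gbest-operator state."""

    positions: np.ndarray       # (N, n)
    velocities: np.ndarray      # (N, n)
    pbest: np.ndarray           # (N, n) personal best positions
    pbest_fitness: np.ndarray   # (N,)
    fitness: np.ndarray         # (N,)


@dataclass
class OptimizerTrace:
    """Per-iteration best-so-far fitness and phase labels of one run."""

    best_fitness: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)
    gbest_position: np.ndarray | None = None
    gbest_fitness: float = -np.inf


def init_population(
    cfg: OptimizerConfig, bounds: SearchBounds, rng: np.random.Generator
) -> Population:
    """Uniform positions ``rand·(UB−LB)+LB``; zero velocities; Pbest = start."""
    shape = (cfg.population, bounds.dimension)
    x = rng.random(shape) * (bounds.upper - bounds.lower) + bounds.lower
    return Population(
        positions=x,
        velocities=np.zeros(shape),
        pbest=x.copy(),
        pbest_fitness=np.full(cfg.population, -np.inf),
        fitness=np.full(cfg.population, -np.inf),
    )


def evolutionary_sense(t: int, T: int, r3: float) -> float:
    """ES(t) = 2·r3·(1 − t/T): stochastic schedule shrinking from ±2 to 0."""
    return 2.0 * r3 * (1.0 - t / T)


def reduction_function(best_j: float, x_r2j: float, epsilon: float) -> float:
    """R = (best_j − x_{r2,j}) / (best_j + ε): narrows the search region."""
    return (best_j - x_r2j) / (best_j + epsilon)


def percentage_difference(
    x_ij: float, mean_xi: float, best_j: float, bounds: SearchBounds,
    alpha: float, epsilon: float,
) -> float:
    """P = α + (x_ij − mean(x_i)) / (best_j·(UB−LB) + ε)."""
    return alpha + (x_ij - mean_xi) / (best_j * (bounds.upper - bounds.lower) + epsilon)


def mean_position(x_i: np.ndarray) -> float:
    """Arithmetic mean of a candidate's coordinates."""
    return float(np.mean(x_i))


def phase_of(t: int, T: int) -> str:
    """Active strategy at 1-based iteration ``t`` (half-open quarters)."""
    q = T // 4
    if t <= q:
        return "high_walk"
    if t <= 2 * q:
        return "belly_walk"
    if t <= 3 * q:
        return "hunt_coordination"
    return "hunt_cooperation"


def phase_update(
    i: int,
    positions: np.ndarray,
    best: np.ndarray,
    t: int,
    T: int,
    cfg: OptimizerConfig,
    bounds: SearchBounds,
    rng: np.random.Generator,
    es: float | None = None,
) -> np.ndarray:
    """New (clamped) position of candidate ``i`` under the active strategy.

    ``positions`` is the whole population snapshot — the belly walk and the
    reduction function reference randomly chosen other candidates.  ``es``
    is the iteration's evolutionary-sense value; drawn here if not given.
    """
    n = positions.shape[1]
    N = positions.shape[0]
    x = positions[i]
    phase = phase_of(t, T)
    eps = cfg.epsilon

    mean_xi = mean_position(x)
    span = best * (bounds.upper - bounds.lower) + eps
    P = cfg.alpha + (x - mean_xi) / span
    eta = best * P
    r2 = rng.integers(0, N, size=n)
    R = (best - positions[r2, np.arange(n)]) / (best + eps)

    if phase == "high_walk":
        new = best * eta * cfg.beta - R * rng.random(n)
    elif phase == "belly_walk":
        if es is None:
            es = evolutionary_sense(t, T, rng.uniform(-1.0, 1.0))
        r1 = int(rng.integers(0, N))
        new = best * positions[r1] * es * rng.random(n)
    elif phase == "hunt_coordination":
        new = best * P * rng.random(n)
    else:  # hunt_cooperation
        new = best - eta * eps - R * rng.random(n)
    return np.clip(new, bounds.lower, bounds.upper)


def gbest_update(
    position: np.ndarray,
    velocity: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    bounds: SearchBounds,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """PSO velocity/position step toward the personal and global bests."""
    n = position.shape[0]
    v = (
        w * velocity
        + c1 * rng.random(n) * (pbest - position)
        + c2 * rng.random(n) * (gbest - position)
    )
    x = np.clip(position + v, bounds.lower, bounds.upper)
    return v, x


def decode_thresholds(position: np.ndarray, n_levels: int = N_LEVELS) -> ThresholdVector:
    """Continuous position → valid strictly increasing integer thresholds.

    Clamp to [1, L−1], round half-up, sort; duplicates move to the next
    free level above, wrapping downward when the top is exhausted.
    """
    pos = np.atleast_1d(np.asarray(position, dtype=float))
    if pos.size >= n_levels - 1:
        raise ValueError(
            f"{pos.size} thresholds do not fit in [1, {n_levels - 1}]"
        )
    vals = np.floor(np.clip(pos, 1, n_levels - 1) + 0.5).astype(int)
    vals = np.clip(vals, 1, n_levels - 1)
    vals.sort()
    used: set[int] = set()
    out: list[int] = []
    for v in vals:
        if v not in used:
            used.add(v)
            out.append(v)
            continue
        up = v + 1
        while up <= n_levels - 1 and up in used:
            up += 1
        if up <= n_levels - 1:
            used.add(up)
            out.append(up)
        else:
            down = v - 1
            while down >= 1 and down in used:
                down -= 1
            if down < 1:
                raise ValueError("no free level left while resolving duplicates")
            used.add(down)
            out.append(down)
    return ThresholdVector(tuple(sorted(out)))


def optimize(
    h: ChannelHistogram,
    k: int,
    objective: str | Callable[[ThresholdVector], float] = "otsu",
    cfg: OptimizerConfig | None = None,
    seed: int | None = None,
) -> tuple[ThresholdVector, float, OptimizerTrace]:
    """Run RSA-Gbest on a histogram; return decoded Gbest, fitness, trace.

    ``objective`` is ``"otsu"``, ``"kapur"``, or any callable mapping a
    ``ThresholdVector`` to a fitness to maximize.  ``seed`` overrides
    ``cfg.seed``; identical (inputs, config, seed) give identical outputs.
    """
    cfg = cfg or OptimizerConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if k < 1 or k > N_LEVELS - 2:
        raise ValueError(f"k must be in [1, {N_LEVELS - 2}]")
    if callable(objective):
        fit_fn = objective
    else:
        ev = ObjectiveEvaluator(h, objective)
        fit_fn = lambda tv: ev(tv.values)  # noqa: E731

    rng = np.random.default_rng(cfg.seed)
    bounds = SearchBounds(1.0, float(N_LEVELS - 1), k)
    pop = init_population(cfg, bounds, rng)
    N, T = cfg.population, cfg.iterations

    def evaluate(x: np.ndarray) -> float:
        return float(fit_fn(decode_thresholds(x)))

    for i in range(N):
        pop.fitness[i] = evaluate(pop.positions[i])
    pop.pbest_fitness[:] = pop.fitness

    g = int(np.argmax(pop.fitness))
    gbest = pop.positions[g].copy()
    gbest_f = float(pop.fitness[g])
    trace = OptimizerTrace()

    for t in range(1, T + 1):
        phase = phase_of(t, T)
        es = evolutionary_sense(t, T, rng.uniform(-1.0, 1.0))
        w = cfg.w_max - (cfg.w_max - cfg.w_min) * (t - 1) / max(T - 1, 1)
        snapshot = pop.positions.copy()
        for i in range(N):
            x_old, f_old = pop.positions[i], float(pop.fitness[i])
            x_rsa = phase_update(i, snapshot, gbest, t, T, cfg, bounds, rng, es=es)
            f_rsa = evaluate(x_rsa)
            v_new, x_pso = gbest_update(
                x_old, pop.velocities[i], pop.pbest[i], gbest,
                w, cfg.c1, cfg.c2, bounds, rng,
            )
            f_pso = evaluate(x_pso)
            pop.velocities[i] = v_new
            # greedy selection: keep the best of {old, RSA move, Gbest move}
            if f_rsa >= f_old and f_rsa >= f_pso:
                pop.positions[i], pop.fitness[i] = x_rsa, f_rsa
            elif f_pso >= f_old:
                pop.positions[i], pop.fitness[i] = x_pso, f_pso
            best_new = max(f_rsa, f_pso)
            if best_new > pop.pbest_fitness[i]:
                pop.pbest_fitness[i] = best_new
                pop.pbest[i] = x_rsa if f_rsa >= f_pso else x_pso
            if pop.fitness[i] > gbest_f:
                gbest_f = float(pop.fitness[i])
                gbest = pop.positions[i].copy()
        trace.best_fitness.append(gbest_f)
        trace.phase.append(phase)

    trace.gbest_position = gbest
    trace.gbest_fitness = gbest_f
    best_t = decode_thresholds(gbest)
    return best_t, float(fit_fn(best_t)), trace


def optimize_runs(
    h: ChannelHistogram,
    k: int,
    objective: str = "otsu",
    cfg: OptimizerConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> list[tuple[ThresholdVector, float, OptimizerTrace]]:
    """Repeat ``optimize`` over independent seeds (default: cfg.runs seeds)."""
    cfg = cfg or OptimizerConfig()
    if seeds is None:
        root = np.random.default_rng(cfg.seed)
        seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=cfg.runs)]
    return [optimize(h, k, objective, cfg, seed=s) for s in seeds]
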
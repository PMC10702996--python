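"""Improved Dwarf Mongoose Optimization (IDMO): a bound-constrained
continuous minimizer with full trace logging.

The population of candidate solutions ("mongooses") is an n×d matrix inside a
box [L, U].  Each iteration runs three phases mimicking the social foraging
of dwarf mongooses:

* **alpha phase** — the fittest individual (the alpha) guides moves
  ``x' = alpha + omega * phi * rand * (x_a - x_u)`` with ``phi`` drawn
  uniformly from a symmetric range and ``omega = exp(-4 (C/Max)^2)`` an
  iteration-dependent step damper;
* **scout phase** — diversification moves
  ``x' = alpha + phi * rand * (x_u - x_v) / 2`` toward unexplored regions;
* **babysitter phase** — every ``timer`` iterations the worst third of the
  population (the babysitters) is exchanged:
  ``x' = x_b + CF * rand * (alpha - (x_u + x_v)/2) * br`` with
  ``CF = (1 - C/Max)^(2 C/Max)`` and birthrate ``br``.

Alpha and scout moves use greedy (keep-if-better) acceptance; the babysitter
exchange is an unconditional replacement.  All candidates are clipped to the
box.  The run is fully deterministic given the seed, and the best-so-far
incumbent is monotone non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IDMOConfig",
    "MongoosePopulation",
    "omega",
    "babysitter_cf",
    "init_population",
    "select_alpha",
    "alpha_phase",
    "scout_phase",
    "babysitter_phase",
    "optimize",
    "random_search",
    "BENCHMARKS",
    "sphere",
    "rastrigin",
    "rosenbrock",
    "ackley",
]


@dataclass
class IDMOConfig:
    n: int = 30
    max_iter: int = 100
    phi_range: tuple[float, float] = (-1.0, 1.0)
    br: float | None = None          # None: drawn Uniform[0,1] per update
    use_omega: bool = True
    babysitter_fraction: float = 1.0 / 3.0
    babysitter_timer: int = 6
    bound_handling: str = "clip"     # or "resample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("population size n must be >= 4")
        if self.bound_handling not in ("clip", "resample"):
            raise ValueError(f"unknown bound_handling {self.bound_handling!r}")


@dataclass
class MongoosePopulation:
    positions: np.ndarray            # (n, d)
    fitness: np.ndarray              # (n,)
    lower: np.ndarray                # (d,)
    upper: np.ndarray                # (d,)
    alpha_index: int
    babysitters: np.ndarray          # indices of the current babysitter set
    babysitter_timer: int
    c_iter: int = 0
    max_iter: int = 0
    eval_count: int = 0
    best_position: np.ndarray | None = None
    best_fitness: float = np.inf
    bound_handling: str = "clip"
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]

    def evaluate(self, objective, x: np.ndarray) -> float:
        val = float(objective(x))
        if np.isnan(val):
            raise ValueError(f"objective returned NaN at position {x!r}")
        self.eval_count += 1
        if val < self.best_fitness:
            self.best_fitness = val
            self.best_position = x.copy()
        return val

    def clip(self, x: np.ndarray) -> np.ndarray:
        if self.bound_handling == "resample":
            out = (x < self.lower) | (x > self.upper)
            if out.any():
                x = x.copy()
                redraw = self.rng.random(int(out.sum()))
                x[out] = redraw * (self.upper - self.lower)[out] + self.lower[out]
            return x
        return np.clip(x, self.lower, self.upper)


def omega(c_iter: int, max_iter: int) -> float:
    """Step damper omega = exp(-4 (C_iter/Max_iter)^2): 1 at start, e^-4 at end."""
    return float(np.exp(-4.0 * (c_iter / max_iter) ** 2))


def babysitter_cf(c_iter: int, max_iter: int) -> float:
    """Exchange scale CF = (1 - C/Max)^(2 C/Max): 1 at start, 0 at end."""
    frac = c_iter / max_iter
    return float((1.0 - frac) ** (2.0 * frac))


def _worst_third(fitness: np.ndarray, fraction: float) -> np.ndarray:
    n = len(fitness)
    n_b = max(1, int(round(n * fraction)))
    order = np.argsort(fitness, kind="stable")
    return np.sort(order[n - n_b:])


def init_population(config: IDMOConfig, objective, bounds) -> MongoosePopulation:
    """Uniform initialization inside the box, one evaluation per individual."""
    lower, upper = (np.asarray(b, dtype=np.float64) for b in bounds)
    if lower.shape != upper.shape:
        raise ValueError("bound shapes differ")
    if not np.all(lower < upper):
        raise ValueError("lower bound must be strictly below upper in every dimension")
    rng = np.random.default_rng(config.seed)
    d = lower.size
    X = rng.random((config.n, d)) * (upper - lower) + lower
    pop = MongoosePopulation(
        positions=X,
        fitness=np.empty(config.n),
        lower=lower,
        upper=upper,
        alpha_index=0,
        babysitters=np.empty(0, dtype=int),
        babysitter_timer=config.babysitter_timer,
        bound_handling=config.bound_handling,
        rng=rng,
    )
    for i in range(config.n):
        pop.fitness[i] = pop.evaluate(objective, X[i])
    pop.alpha_index = select_alpha(pop)
    pop.babysitters = _worst_third(pop.fitness, config.babysitter_fraction)
    return pop


def select_alpha(population: MongoosePopulation) -> int:
    """Index of the fittest individual (minimum fitness; ties -> lowest index)."""
    fit = population.fitness
    if np.isnan(fit).any():
        raise ValueError("fitness vector contains NaN")
    return int(np.argmin(fit))


def _foragers(pop: MongoosePopulation) -> np.ndarray:
    mask = np.ones(pop.n, dtype=bool)
    mask[pop.babysitters] = False
    return np.flatnonzero(mask)


def _propose_alpha(pop, config, a: int) -> np.ndarray:
    alpha_pos = pop.positions[pop.alpha_index]
    phi = pop.rng.uniform(*config.phi_range)
    r = pop.rng.random()
    peers = np.delete(np.arange(pop.n), a)
    u = int(pop.rng.choice(peers))
    step = phi * r * (pop.positions[a] - pop.positions[u])
    if config.use_omega:
        step = omega(pop.c_iter, pop.max_iter) * step
    return alpha_pos + step


def _propose_scout(pop, config, a: int) -> np.ndarray:
    alpha_pos = pop.positions[pop.alpha_index]
    phi = pop.rng.uniform(*config.phi_range)
    r = pop.rng.random()
    peers = np.delete(np.arange(pop.n), a)
    u, v = pop.rng.choice(peers, size=2, replace=False)
    return alpha_pos + phi * r * (pop.positions[int(u)] - pop.positions[int(v)]) / 2.0


def _greedy_phase(pop: MongoosePopulation, config: IDMOConfig, objective,
                  propose) -> MongoosePopulation:
    foragers = _foragers(pop)
    for a in foragers:
        cand = pop.clip(propose(pop, config, int(a)))
        f_cand = pop.evaluate(objective, cand)
        if f_cand < pop.fitness[a]:
            pop.positions[a] = cand
            pop.fitness[a] = f_cand
    pop.alpha_index = select_alpha(pop)
    return pop


def alpha_phase(pop: MongoosePopulation, config: IDMOConfig, objective):
    """Alpha-guided foraging with greedy acceptance."""
    if len(_foragers(pop)) < 2:
        raise ValueError("alpha phase needs at least 2 non-babysitters")
    return _greedy_phase(pop, config, objective, _propose_alpha)


def scout_phase(pop: MongoosePopulation, config: IDMOConfig, objective):
    """Scouting toward new sleeping mounds; diversification moves."""
    if pop.n < 3:
        raise ValueError("scout phase needs n >= 3")
    return _greedy_phase(pop, config, objective, _propose_scout)


def babysitter_phase(pop: MongoosePopulation, config: IDMOConfig, objective):
    """Countdown-gated exchange of the worst-fitness third of the population."""
    n_b = max(1, int(round(pop.n * config.babysitter_fraction)))
    if n_b >= pop.n:
        raise ValueError("babysitter count must be below the population size")
    pop.babysitter_timer -= 1
    exchanged = False
    if pop.babysitter_timer <= 0:
        exchanged = True
        pop.babysitters = _worst_third(pop.fitness, config.babysitter_fraction)
        alpha_pos = pop.positions[pop.alpha_index]
        non_b = _foragers(pop)
        cf = babysitter_cf(pop.c_iter, pop.max_iter) if config.use_omega else 1.0
        for b in pop.babysitters:
            br = config.br if config.br is not None else pop.rng.random()
            r = pop.rng.random()
            u, v = pop.rng.choice(non_b, size=2, replace=False)
            mid = (pop.positions[int(u)] + pop.positions[int(v)]) / 2.0
            cand = pop.clip(pop.positions[b] + cf * r * (alpha_pos - mid) * br)
            pop.positions[b] = cand
            pop.fitness[b] = pop.evaluate(objective, cand)
        pop.babysitter_timer = config.babysitter_timer
        pop.alpha_index = select_alpha(pop)
    return pop, exchanged


def optimize(objective, bounds, config: IDMOConfig | None = None):
    """Run the full three-phase loop for max_iter iterations.

    Returns (best_position, best_fitness, trace) where trace is a DataFrame
    with one row per iteration: iteration, best_fitness (best-so-far),
    mean_fitness, evaluations, exchanged.
    """
    config = config or IDMOConfig()
    pop = init_population(config, objective, bounds)
    pop.max_iter = config.max_iter
    rows = []
    for it in range(config.max_iter):
        pop.c_iter = it
        alpha_phase(pop, config, objective)
        scout_phase(pop, config, objective)
        _, exchanged = babysitter_phase(pop, config, objective)
        rows.append({
            "iteration": it + 1,
            "best_fitness": pop.best_fitness,
            "mean_fitness": float(pop.fitness.mean()),
            "evaluations": pop.eval_count,
            "exchanged": exchanged,
        })
    trace = pd.DataFrame(rows)
    return pop.best_position, pop.best_fitness, trace


def random_search(objective, bounds, n_evals: int, seed: int = 0):
    """Budget-matched uniform random search baseline."""
    lower, upper = (np.asarray(b, dtype=np.float64) for b in bounds)
    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    for _ in range(n_evals):
        x = rng.random(lower.size) * (upper - lower) + lower
        f = float(objective(x))
        if f < best_f:
            best_f, best_x = f, x
    return best_x, best_f


# ---------------------------------------------------------------------------
# Benchmark suite

def sphere(x):
    x = np.asarray(x)
    return float(np.sum(x**2))


def rastrigin(x):
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2 * np.pi * x)))


def rosenbrock(x):
    x = np.asarray(x)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2))


def ackley(x):
    x = np.asarray(x)
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / d))
        - np.exp(np.sum(np.cos(2 * np.pi * x)) / d) + 20.0 + np.e
    )


BENCHMARKS = {
    "sphere": (sphere, (-5.0, 5.0)),
    "rastrigin": (rastrigin, (-5.12, 5.12)),
    "rosenbrock": (rosenbrock, (-5.0, 10.0)),
    "ackley": (ackley, (-32.0, 32.0)),
}
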
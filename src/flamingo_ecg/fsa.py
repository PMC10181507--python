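"""Flamingo search algorithm (FSA): a bounded continuous population metaheuristic.

The flock alternates between two moves each iteration:

* **foraging** (bill-scanning + claw-locomotive): each selected flamingo
  moves per coordinate ``y' = (y + lam1 * y_s + M2 * |M1 * y_d + lam1 + y|) / R``
  where ``y_s`` is the current-iteration best position, ``y_d`` the best
  position ever visited ("abundance of food"), ``lam1 ~ U[-1, 1]``,
  ``M1, M2 ~ N(0, 1)`` and ``R`` a chi-square(q) diffusion factor drawn once
  per flamingo;
* **emigration**: the remaining flamingos drift toward the best solution
  found so far, ``y' = y + sigma * (y_d - y)`` with ``sigma ~ N(0, q)`` per
  coordinate; the contractive draws concentrate the flock around the best
  position and supply local refinement.

The best-ever position is tracked elitistically, so the best-so-far fitness
trace is monotone under the optimization sense.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "FSAConfig",
    "FlamingoPopulation",
    "RandomDraws",
    "OptimizationResult",
    "EvaluationError",
    "sample_diffusion_factor",
    "init_population",
    "foraging_update",
    "emigration_update",
    "run_fsa",
]

_R_FLOOR = 1e-12  # keeps the Eq-5 style division finite; chi-square(q) is a.s. > 0


class EvaluationError(RuntimeError):
    """The objective returned a non-finite value at an in-bounds position."""

    def __init__(self, position: np.ndarray, value: float):
        self.position = np.asarray(position)
        self.value = value
        super().__init__(
            f"objective returned non-finite value {value!r} at position "
            f"{np.array2string(self.position, precision=6)}"
        )


@dataclass(frozen=True)
class ObjectiveSpec:
    """A bounded scalar objective.

    Parameters
    ----------
    evaluate:
        Maps a position vector of length ``dims`` to a finite scalar.
    lower_bounds, upper_bounds:
        Box constraints, elementwise ``lower < upper``.
    sense:
        ``"min"`` (default) or ``"max"``.
    """

    evaluate: Callable[[np.ndarray], float]
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    sense: str = "min"

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
            raise ValueError("bounds must be finite")
        if not (lo < hi).all():
            raise ValueError("lower_bounds must be < upper_bounds elementwise")
        if self.sense not in ("min", "max"):
            raise ValueError(f"sense must be 'min' or 'max', got {self.sense!r}")

    @property
    def dims(self) -> int:
        return self.lower_bounds.size

    def is_better(self, a: float, b: float) -> bool:
        """True when fitness ``a`` beats fitness ``b`` under this sense."""
        return a < b if self.sense == "min" else a > b

    def __call__(self, position: np.ndarray) -> float:
        value = float(self.evaluate(np.asarray(position, dtype=float)))
        if not np.isfinite(value):
            raise EvaluationError(position, value)
        return value


@dataclass(frozen=True)
class FSAConfig:
    """Run-time knobs of the flamingo search.

    ``chi_square_dof`` (q) controls both the diffusion factor R ~ chi2(q)
    and the emigration scale sigma ~ N(0, q). ``foraging_fraction`` of the
    flock does the foraging move each iteration; the rest emigrate.
    ``divide_by_r`` selects division by the diffusion factor (default) or the
    multiply variant for sensitivity analysis. ``m_distribution`` switches
    M1/M2 between standard normal (default) and standard uniform draws.
    """

    population_size: int = 30
    max_iterations: int = 500
    foraging_fraction: float = 0.4
    chi_square_dof: int = 4
    seed: int = 0
    bound_policy: str = "clip"
    divide_by_r: bool = True
    m_distribution: str = "normal"

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.foraging_fraction <= 1.0:
            raise ValueError("foraging_fraction must be in (0, 1]")
        if self.chi_square_dof < 1:
            raise ValueError("chi_square_dof must be >= 1")
        if self.bound_policy not in ("clip", "reflect"):
            raise ValueError("bound_policy must be 'clip' or 'reflect'")
        if self.m_distribution not in ("normal", "uniform"):
            raise ValueError("m_distribution must be 'normal' or 'uniform'")


@dataclass
class RandomDraws:
    """One batch of stochastic factors for an update step.

    Arrays are broadcast against the ``(n_moving, dims)`` position block.
    Used internally with fresh draws; tests may inject degenerate values to
    check the closed-form reductions of the update rules.
    """

    m1: np.ndarray | float = 0.0
    m2: np.ndarray | float = 0.0
    lambda1: np.ndarray | float = 0.0
    r: np.ndarray | float = 1.0
    sigma: np.ndarray | float = 0.0


@dataclass
class FlamingoPopulation:
    """Positions and fitness of the flock plus best-so-far bookkeeping.

    ``best_position``/``best_fitness`` track the current-iteration best
    (y_s); ``food_position``/``food_fitness`` track the elitist best ever
    evaluated (y_d), never overwritten by a worse solution.
    """

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    food_position: np.ndarray
    food_fitness: float
    iteration: int = 0
    evaluations: int = 0

    def refresh_best(self, objective: ObjectiveSpec) -> None:
        idx = (
            int(np.argmin(self.fitness))
            if objective.sense == "min"
            else int(np.argmax(self.fitness))
        )
        self.best_position = self.positions[idx].copy()
        self.best_fitness = float(self.fitness[idx])
        if objective.is_better(self.best_fitness, self.food_fitness):
            self.food_position = self.best_position.copy()
            self.food_fitness = self.best_fitness


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    mean_history: np.ndarray
    evaluation_history: np.ndarray
    evaluations: int
    seed: int

    def write_trace(self, path) -> None:
        """CSV trace: iteration, best_fitness, mean_fitness, evaluations."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "best_fitness", "mean_fitness", "evaluations"])
            for i, (b, m, e) in enumerate(
                zip(self.history, self.mean_history, self.evaluation_history), start=1
            ):
                writer.writerow([i, repr(float(b)), repr(float(m)), int(e)])


def sample_diffusion_factor(q: int, rng: np.random.Generator, size=None) -> np.ndarray | float:
    """Draw the diffusion factor R ~ chi-square(q); strictly positive."""
    if q < 1:
        raise ValueError("chi-square degrees of freedom must be >= 1")
    draw = rng.chisquare(q, size=size)
    return np.maximum(draw, _R_FLOOR)


def _map_to_bounds(positions: np.ndarray, objective: ObjectiveSpec, policy: str) -> np.ndarray:
    lo, hi = objective.lower_bounds, objective.upper_bounds
    if policy == "clip":
        return np.clip(positions, lo, hi)
    # reflect: fold into the box; period 2*(hi-lo) handles arbitrarily far excursions
    span = hi - lo
    folded = np.mod(positions - lo, 2.0 * span)
    reflected = np.where(folded > span, 2.0 * span - folded, folded)
    return lo + reflected


def _evaluate_rows(positions: np.ndarray, objective: ObjectiveSpec) -> np.ndarray:
    return np.array([objective(row) for row in positions], dtype=float)


def init_population(
    objective: ObjectiveSpec, config: FSAConfig, rng: np.random.Generator | None = None
) -> FlamingoPopulation:
    """Uniform seeded initialization within bounds; evaluates the whole flock."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = rng.uniform(
        objective.lower_bounds,
        objective.upper_bounds,
        size=(config.population_size, objective.dims),
    )
    fitness = _evaluate_rows(positions, objective)
    pop = FlamingoPopulation(
        positions=positions,
        fitness=fitness,
        best_position=positions[0].copy(),
        best_fitness=float(fitness[0]),
        food_position=positions[0].copy(),
        food_fitness=float(fitness[0]),
        iteration=0,
        evaluations=config.population_size,
    )
    pop.food_fitness = np.inf if objective.sense == "min" else -np.inf
    pop.refresh_best(objective)
    return pop


def _draw_foraging(
    n: int, k: int, config: FSAConfig, rng: np.random.Generator
) -> RandomDraws:
    if config.m_distribution == "normal":
        m1 = rng.standard_normal((n, k))
        m2 = rng.standard_normal((n, k))
    else:
        m1 = rng.uniform(0.0, 1.0, (n, k))
        m2 = rng.uniform(0.0, 1.0, (n, k))
    lambda1 = rng.uniform(-1.0, 1.0, (n, k))
    r = sample_diffusion_factor(config.chi_square_dof, rng, size=(n, 1))
    return RandomDraws(m1=m1, m2=m2, lambda1=lambda1, r=r)


def foraging_update(
    pop: FlamingoPopulation,
    objective: ObjectiveSpec,
    config: FSAConfig,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    draws: RandomDraws | None = None,
) -> FlamingoPopulation:
    """Bill-scanning + claw-locomotive move for the foraging subset.

    M1/M2/lambda1 are drawn per flamingo per coordinate, R once per flamingo.
    ``draws`` overrides the fresh draws (used to verify reductions such as
    lambda1 = M2 = 0, R = 1 leaving positions unchanged).
    """
    if indices is None:
        n_forage = int(np.ceil(config.foraging_fraction * config.population_size))
        indices = np.arange(n_forage)
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        return pop
    y = pop.positions[indices]
    if draws is None:
        draws = _draw_foraging(indices.size, objective.dims, config, rng)
    y_s = pop.best_position
    y_d = pop.food_position
    step = draws.lambda1 * y_s + draws.m2 * np.abs(draws.m1 * y_d + draws.lambda1 + y)
    moved = y + step
    r = np.maximum(np.asarray(draws.r, dtype=float), _R_FLOOR)
    moved = moved / r if config.divide_by_r else moved * r
    moved = _map_to_bounds(moved, objective, config.bound_policy)
    pop.positions[indices] = moved
    pop.fitness[indices] = _evaluate_rows(moved, objective)
    pop.evaluations += indices.size
    pop.refresh_best(objective)
    return pop


def emigration_update(
    pop: FlamingoPopulation,
    objective: ObjectiveSpec,
    config: FSAConfig,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    draws: RandomDraws | None = None,
) -> FlamingoPopulation:
    """Emigration move toward the best-ever (food) position, one sigma per
    coordinate; draws near sigma = 1 land emigrants on the food position."""
    if indices is None:
        n_forage = int(np.ceil(config.foraging_fraction * config.population_size))
        indices = np.arange(n_forage, config.population_size)
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        return pop
    y = pop.positions[indices]
    if draws is None:
        sigma = rng.normal(
            0.0, np.sqrt(config.chi_square_dof), size=(indices.size, objective.dims)
        )
    else:
        sigma = np.asarray(draws.sigma, dtype=float)
    moved = y + sigma * (pop.food_position - y)
    moved = _map_to_bounds(moved, objective, config.bound_policy)
    pop.positions[indices] = moved
    pop.fitness[indices] = _evaluate_rows(moved, objective)
    pop.evaluations += indices.size
    pop.refresh_best(objective)
    return pop


def run_fsa(objective: ObjectiveSpec, config: FSAConfig) -> OptimizationResult:
    """Full flamingo search: init, then foraging + emigration each iteration.

    Returns the elitist best over all evaluations with a per-iteration
    best-so-far history; bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(objective, config, rng)
    history = np.empty(config.max_iterations)
    mean_history = np.empty(config.max_iterations)
    eval_history = np.empty(config.max_iterations, dtype=int)
    n_forage = int(np.ceil(config.foraging_fraction * config.population_size))
    for n in range(config.max_iterations):
        order = rng.permutation(config.population_size)
        foraging_update(pop, objective, config, rng, indices=order[:n_forage])
        emigration_update(pop, objective, config, rng, indices=order[n_forage:])
        pop.iteration = n + 1
        history[n] = pop.food_fitness
        mean_history[n] = float(np.mean(pop.fitness))
        eval_history[n] = pop.evaluations
    return OptimizationResult(
        best_position=pop.food_position.copy(),
        best_fitness=float(pop.food_fitness),
        history=history,
        mean_history=mean_history,
        evaluation_history=eval_history,
        evaluations=int(pop.evaluations),
        seed=config.seed,
    )
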
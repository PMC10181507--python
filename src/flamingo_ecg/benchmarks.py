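"""Benchmark objectives for exercising the flamingo search optimizer."""

from __future__ import annotations

import numpy as np

from .fsa import ObjectiveSpec

__all__ = [
    "rosenbrock_fitness",
    "sphere_fitness",
    "rastrigin_fitness",
    "make_objective",
    "BENCHMARKS",
]


def rosenbrock_fitness(position: np.ndarray) -> float:
    """2-D Rosenbrock valley f(x) = 100 (x1^2 - x2)^2 + (1 - x1)^2.

    Global minimum 0 at (1, 1); always nonnegative.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (2,):
        raise ValueError(f"rosenbrock expects a 2-vector, got shape {position.shape}")
    x1, x2 = position
    return float(100.0 * (x1**2 - x2) ** 2 + (1.0 - x1) ** 2)


def sphere_fitness(position: np.ndarray) -> float:
    """Sum of squares; minimum 0 at the origin, any dimension."""
    position = np.asarray(position, dtype=float)
    return float(np.sum(position**2))


def rastrigin_fitness(position: np.ndarray) -> float:
    """Highly multimodal Rastrigin function; minimum 0 at the origin."""
    x = np.asarray(position, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


BENCHMARKS = {
    "rosenbrock": (rosenbrock_fitness, 2, (-5.0, 5.0)),
    "sphere": (sphere_fitness, 5, (-5.0, 5.0)),
    "rastrigin": (rastrigin_fitness, 5, (-5.12, 5.12)),
}


def make_objective(name: str, dims: int | None = None, bounds=None) -> ObjectiveSpec:
    """Build an ObjectiveSpec for a named benchmark."""
    if name not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    fn, default_dims, default_bounds = BENCHMARKS[name]
    k = default_dims if dims is None else int(dims)
    if name == "rosenbrock" and k != 2:
        raise ValueError("rosenbrock benchmark is 2-D")
    lo, hi = default_bounds if bounds is None else bounds
    return ObjectiveSpec(
        evaluate=fn,
        lower_bounds=np.full(k, float(lo)),
        upper_bounds=np.full(k, float(hi)),
        sense="min",
    )
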
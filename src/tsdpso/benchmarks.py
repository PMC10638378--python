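"""Classical test functions for validating continuous optimizers.

Six minimization benchmarks (Griewank, Rastrigin, Alpine, Ackley,
Rosenbrock, Sphere), each with conventional box bounds and a known global
optimum.  All standard forms are non-negative and attain 0 at their
optimum, which makes them convenient yardsticks for swarm optimizers.

Ackley and Rosenbrock additionally expose an ``as_printed`` variant that
reproduces two corrupted renderings sometimes seen in the applied
literature (a ``cos(pi*i)`` term constant in x, and a Rosenbrock missing
the square on ``x_i``).  The standard forms are the default and the only
ones whose registered optimum is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BenchmarkFunction",
    "benchmark_registry",
    "get_benchmark",
    "evaluate_benchmark",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """Descriptor of a scalar test function on a symmetric box."""

    name: str
    evaluate: Callable[[np.ndarray], float]
    default_bound: float  # box is [-default_bound, default_bound]^n
    known_optimum_value: float = 0.0
    optimum_coordinate: float = 0.0  # optimum is (c, c, ..., c)
    aliases: tuple[str, ...] = field(default=())

    def bounds(self, dimension: int) -> tuple[np.ndarray, np.ndarray]:
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        b = self.default_bound
        return -b * np.ones(dimension), b * np.ones(dimension)

    def known_optimum_point(self, dimension: int) -> np.ndarray:
        return np.full(dimension, self.optimum_coordinate)


def _as_vector(x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-D vector")
    return x


def sphere(x: Sequence[float]) -> float:
    x = _as_vector(x)
    return float(np.sum(x * x))


def griewank(x: Sequence[float]) -> float:
    x = _as_vector(x)
    i = np.arange(1, x.size + 1)
    return float(1.0 + np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))))


def rastrigin(x: Sequence[float]) -> float:
    x = _as_vector(x)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def alpine(x: Sequence[float]) -> float:
    x = _as_vector(x)
    return float(np.sum(np.abs(x * np.sin(x) + 0.1 * x)))


def ackley(x: Sequence[float], variant: str = "standard") -> float:
    x = _as_vector(x)
    n = x.size
    first = -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
    if variant == "standard":
        second = -np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
    elif variant == "as_printed":
        # cos(pi*i) over the index i: constant in x, kept only for fidelity runs
        i = np.arange(1, n + 1)
        second = -np.exp(np.sum(np.cos(np.pi * i)) / n)
    else:
        raise ValueError(f"unknown Ackley variant {variant!r}")
    return float(first + second + 20.0 + np.e)


def rosenbrock(x: Sequence[float], variant: str = "standard") -> float:
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("Rosenbrock needs dimension >= 2")
    head, tail = x[:-1], x[1:]
    if variant == "standard":
        return float(np.sum(100.0 * (tail - head**2) ** 2 + (head - 1.0) ** 2))
    if variant == "as_printed":
        return float(np.sum(100.0 * (tail - head) ** 2 + (head - 1.0) ** 2))
    raise ValueError(f"unknown Rosenbrock variant {variant!r}")


_REGISTRY: dict[str, BenchmarkFunction] = {}


def _register(fn: BenchmarkFunction) -> None:
    _REGISTRY[fn.name] = fn


_register(BenchmarkFunction("griewank", griewank, 600.0))
_register(BenchmarkFunction("rastrigin", rastrigin, 5.12, aliases=("rastigin",)))
_register(BenchmarkFunction("alpine", alpine, 10.0))
_register(BenchmarkFunction("ackley", ackley, 32.0))
_register(
    BenchmarkFunction(
        "rosenbrock", rosenbrock, 30.0, optimum_coordinate=1.0
    )
)
_register(BenchmarkFunction("sphere", sphere, 30.0))


def benchmark_registry() -> list[BenchmarkFunction]:
    """All six benchmark descriptors, in registration order."""
    return list(_REGISTRY.values())


def get_benchmark(name: str) -> BenchmarkFunction:
    """Look up a benchmark by case-insensitive name or alias."""
    key = name.strip().lower()
    if key in _REGISTRY:
        return _REGISTRY[key]
    for fn in _REGISTRY.values():
        if key in fn.aliases:
            return fn
    raise KeyError(f"unknown benchmark function {name!r}")


def evaluate_benchmark(
    name: str, x: Sequence[float], variant: str = "standard"
) -> float:
    """Evaluate a registered benchmark at ``x``.

    ``variant`` selects the ``as_printed`` renderings of Ackley and
    Rosenbrock; it is ignored for the other four functions.
    """
    fn = get_benchmark(name)
    xv = _as_vector(x)
    if not np.all(np.isfinite(xv)):
        raise ValueError("x must be finite")
    if fn.name in ("ackley", "rosenbrock"):
        return fn.evaluate(xv, variant=variant)  # type: ignore[call-arg]
    return fn.evaluate(xv)
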
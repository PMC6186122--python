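"""Objective-function contracts, budget accounting, and analytic test functions.

Every optimization run in this package is stated in terms of a hard budget of
objective evaluations.  :class:`EvaluationLedger` is the single unit of
accounting: each objective call goes through :func:`evaluate_with_budget`,
which increments the counter and extends the best-so-far trace.  Convergence
claims are made on the *scaled* trace (best-so-far divided by the trial's
initial best), which always starts at 1.0.

The module also ships the standard analytic benchmark functions (Ackley,
Rastrigin, Eggholder, Styblinski–Tang) with their conventional constants and
search domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BoundsBox",
    "EvaluationLedger",
    "ObjectiveSpec",
    "BudgetExhaustedError",
    "evaluate_with_budget",
    "scaled_error",
    "ackley",
    "rastrigin",
    "eggholder",
    "styblinski_tang",
    "get_objective",
    "TEST_FUNCTIONS",
]


class BudgetExhaustedError(RuntimeError):
    """Raised when an objective call is requested with no budget remaining."""


@dataclass(frozen=True)
class BoundsBox:
    """Box constraints ``lower <= x <= upper`` defining the search domain.

    Parameters
    ----------
    lower, upper
        Per-dimension bound vectors of identical length K, with
        ``lower[d] < upper[d]`` for every dimension.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or upper.ndim != 1 or lower.size != upper.size:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if lower.size < 1:
            raise ValueError("bounds must have dimension >= 1")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def dimension(self) -> int:
        return int(self.lower.size)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` points uniformly from the box, shape ``(n, K)``."""
        return rng.uniform(self.lower, self.upper, size=(n, self.dimension))

    @classmethod
    def cube(cls, lower: float, upper: float, dimension: int) -> "BoundsBox":
        return cls(np.full(dimension, float(lower)), np.full(dimension, float(upper)))


@dataclass
class EvaluationLedger:
    """Budget accounting for objective calls.

    Attributes
    ----------
    budget
        Hard cap N on the number of objective evaluations.
    consumed
        Evaluations used so far; never exceeds ``budget``.
    trace
        Per-evaluation ``(evaluation index, best-so-far value)`` pairs;
        best-so-far is monotone non-increasing by construction.
    """

    budget: int
    consumed: int = 0
    trace: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be a positive integer")

    @property
    def remaining(self) -> int:
        return self.budget - self.consumed

    @property
    def best_value(self) -> float:
        if not self.trace:
            raise ValueError("no evaluations recorded yet")
        return self.trace[-1][1]

    def record(self, value: float) -> None:
        """Account for one evaluation that returned ``value``."""
        if self.consumed >= self.budget:
            raise BudgetExhaustedError(
                f"evaluation budget of {self.budget} exhausted"
            )
        self.consumed += 1
        best = value if not self.trace else min(self.trace[-1][1], value)
        self.trace.append((self.consumed, float(best)))

    def best_so_far(self) -> np.ndarray:
        """The best-so-far values as an array of length ``consumed``."""
        return np.array([v for _, v in self.trace], dtype=float)


@dataclass(frozen=True)
class ObjectiveSpec:
    """A named deterministic objective over a bounded box.

    ``evaluate`` maps a length-K vector to a scalar and must be deterministic
    for a fixed input (stochastic objectives are out of scope).
    """

    name: str
    evaluate: Callable[[np.ndarray], float]
    bounds: BoundsBox

    @property
    def dimension(self) -> int:
        return self.bounds.dimension


def evaluate_with_budget(
    spec: ObjectiveSpec, x: np.ndarray, ledger: EvaluationLedger
) -> float:
    """Evaluate ``spec`` at ``x``, charging one evaluation to ``ledger``.

    Raises
    ------
    BudgetExhaustedError
        If the ledger has no evaluations remaining.
    ValueError
        If ``x`` does not have the objective's dimension.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.dimension,):
        raise ValueError(
            f"expected vector of length {spec.dimension}, got shape {x.shape}"
        )
    if ledger.consumed >= ledger.budget:
        raise BudgetExhaustedError(
            f"evaluation budget of {ledger.budget} exhausted"
        )
    value = float(spec.evaluate(x))
    ledger.record(value)
    return value


def scaled_error(trace: Sequence[float] | np.ndarray) -> np.ndarray:
    """Divide a best-so-far trace by its first value.

    The result starts at exactly 1.0; a trace reaching the optimum of a
    non-negative objective ends at 0.0.  Undefined for a non-positive
    initial value.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    if trace[0] <= 0:
        raise ValueError("scaling undefined for non-positive initial value")
    out = trace / trace[0]
    out[0] = 1.0
    return out


# ---------------------------------------------------------------------------
# Analytic test functions (standard literature forms).
# ---------------------------------------------------------------------------

def ackley(x: np.ndarray, a: float = 20.0, b: float = 0.2, c: float = 2 * np.pi) -> float:
    """Ackley function; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("ackley requires a non-empty vector")
    k = x.size
    term1 = -a * np.exp(-b * np.sqrt(np.mean(x**2)))
    term2 = -np.exp(np.sum(np.cos(c * x)) / k)
    return float(term1 + term2 + a + np.e)


def rastrigin(x: np.ndarray, amplitude: float = 10.0) -> float:
    """Rastrigin function ``A*K + sum(x_d^2 - A*cos(2*pi*x_d))``; minimum 0 at origin."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rastrigin requires a non-empty vector")
    return float(amplitude * x.size + np.sum(x**2 - amplitude * np.cos(2 * np.pi * x)))


def eggholder(x: np.ndarray) -> float:
    """2-D Eggholder function on [-512, 512]^2; known minimum -959.6407."""
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError("eggholder is defined for 2-D vectors only")
    x1, x2 = x
    t1 = -(x2 + 47.0) * np.sin(np.sqrt(abs(x2 + x1 / 2.0 + 47.0)))
    t2 = -x1 * np.sin(np.sqrt(abs(x1 - (x2 + 47.0))))
    return float(t1 + t2)


def styblinski_tang(x: np.ndarray) -> float:
    """Styblinski–Tang function ``0.5 * sum(x_d^4 - 16 x_d^2 + 5 x_d)``.

    Separable: the K-dimensional minimum is K times the 1-D minimum
    (about -39.166 per dimension, at x_d ~ -2.9035).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("styblinski_tang requires a non-empty vector")
    return float(0.5 * np.sum(x**4 - 16.0 * x**2 + 5.0 * x))


#: name -> (callable, conventional lower bound, upper bound, fixed dimension or None)
TEST_FUNCTIONS: dict[str, tuple[Callable[[np.ndarray], float], float, float, int | None]] = {
    "ackley": (ackley, -15.0, 30.0, None),
    "rastrigin": (rastrigin, -5.12, 5.12, None),
    "eggholder": (eggholder, -512.0, 512.0, 2),
    "styblinski_tang": (styblinski_tang, -5.0, 5.0, None),
}


def get_objective(
    name: str,
    dimension: int | None = None,
    lower: float | None = None,
    upper: float | None = None,
) -> ObjectiveSpec:
    """Build an :class:`ObjectiveSpec` for a named test function.

    ``dimension`` is required for the scalable functions and ignored for the
    fixed-dimension ones; ``lower``/``upper`` override the conventional box.
    """
    try:
        func, lo, hi, fixed_dim = TEST_FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown test function {name!r}; available: {sorted(TEST_FUNCTIONS)}"
        ) from None
    if fixed_dim is not None:
        dimension = fixed_dim
    if dimension is None:
        raise ValueError(f"dimension is required for test function {name!r}")
    lo = lo if lower is None else float(lower)
    hi = hi if upper is None else float(upper)
    bounds = BoundsBox.cube(lo, hi, dimension)
    return ObjectiveSpec(name=f"{name}-{dimension}d", evaluate=func, bounds=bounds)
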
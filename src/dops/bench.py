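"""Reference benchmark computations shared by the CLI, tests, and scripts.

These functions reproduce the study conditions the package is validated
against: DOPS with 40 particles in 5 sub-swarms, N = 4000 evaluations,
T = 25 trials, mean final scaled error on the 10-D Ackley and Rastrigin
functions; and the Eggholder global minimum located by dense grid search
plus bounded local refinement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .controller import DOPSConfig
from .harness import batch_summary, run_batch
from .objective import eggholder, get_objective

__all__ = ["benchmark_scaled_error", "eggholder_minimum"]


def benchmark_scaled_error(
    function_name: str,
    dimension: int = 10,
    budget: int = 4000,
    trials: int = 25,
    base_seed: int = 0,
    variant: str = "dops",
) -> dict:
    """Mean final scaled error of a variant on a named test function.

    The per-trial scaled error is the final best objective value divided by
    the best among that trial's randomly initialized particles.
    """
    spec = get_objective(function_name, dimension)
    batch = run_batch(variant, spec, DOPSConfig(total_budget=budget), trials, base_seed)
    if batch.failures:
        raise RuntimeError(f"{len(batch.failures)} trial(s) failed: {batch.failures}")
    return batch_summary(batch)


def eggholder_minimum(grid_points: int = 2049) -> tuple[np.ndarray, float]:
    """Locate the Eggholder global minimum over [-512, 512]^2.

    Dense grid evaluation followed by L-BFGS-B refinement from the best grid
    point.  Returns (argmin, minimum value).
    """
    grid = np.linspace(-512.0, 512.0, grid_points)
    xx, yy = np.meshgrid(grid, grid)
    t1 = -(yy + 47.0) * np.sin(np.sqrt(np.abs(yy + xx / 2.0 + 47.0)))
    t2 = -xx * np.sin(np.sqrt(np.abs(xx - (yy + 47.0))))
    surface = t1 + t2
    flat = int(np.argmin(surface))
    x0 = np.array([xx.ravel()[flat], yy.ravel()[flat]])
    res = minimize(eggholder, x0, method="L-BFGS-B", bounds=[(-512.0, 512.0)] * 2)
    return np.asarray(res.x), float(res.fun)
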
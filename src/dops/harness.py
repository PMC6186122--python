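"""Multi-trial experiment runner and convergence aggregation.

Performance claims are made over T independent seeded trials; each trial gets
its own reproducible random stream derived from a base seed.  Per-trial
best-so-far traces are scaled by the trial's initial best (so every trial
starts at 1.0), aligned on a common evaluation grid by
last-observation-carried-forward, then averaged pointwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import DOPSConfig, OptimizationResult, run_variant
from .objective import ObjectiveSpec, scaled_error

__all__ = [
    "TrialBatch",
    "derive_trial_seeds",
    "run_batch",
    "aggregate_convergence",
    "batch_summary",
    "result_to_json",
    "trace_to_csv",
    "trace_from_csv",
]


def derive_trial_seeds(base_seed: int, trials: int) -> list[int]:
    """Distinct per-trial integer seeds (< 2^31) derived from ``base_seed``."""
    seeds: list[int] = []
    seen: set[int] = set()
    for t in range(trials):
        s = int(np.random.SeedSequence([base_seed, t]).generate_state(1)[0] % (2**31))
        while s in seen:  # vanishingly unlikely, but seeds must be distinct
            s = (s + 1) % (2**31)
        seen.add(s)
        seeds.append(s)
    return seeds


@dataclass
class TrialBatch:
    """Results of T independent seeded runs of one variant on one objective.

    ``baseline_evals`` sets the scaling convention: the "initial best" of a
    trial is the best-so-far after that many evaluations (the NP random
    initialization evaluations for swarm-based variants; the single starting
    point for DDS-only).
    """

    variant: str
    objective_name: str
    dimension: int
    trials: int
    base_seed: int
    results: list[OptimizationResult]
    failures: list[tuple[int, str]]
    baseline_evals: int = 1

    def initial_bests(self) -> np.ndarray:
        idx = self.baseline_evals - 1
        return np.array([r.best_so_far()[idx] for r in self.results])

    def final_values(self) -> np.ndarray:
        return np.array([r.best_value for r in self.results])

    def final_scaled_errors(self) -> np.ndarray:
        return self.final_values() / self.initial_bests()


def run_batch(
    variant: str,
    spec: ObjectiveSpec,
    config: DOPSConfig,
    trials: int,
    base_seed: int,
) -> TrialBatch:
    """Run ``trials`` independent seeded optimizations.

    Individual trial failures are recorded with their error message, never
    silently dropped.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    seeds = derive_trial_seeds(base_seed, trials)
    results: list[OptimizationResult] = []
    failures: list[tuple[int, str]] = []
    for t, seed in enumerate(seeds):
        try:
            results.append(run_variant(variant, spec, replace(config, seed=seed)))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            failures.append((t, f"{type(exc).__name__}: {exc}"))
    return TrialBatch(
        variant=variant,
        objective_name=spec.name,
        dimension=spec.dimension,
        trials=trials,
        base_seed=base_seed,
        results=results,
        failures=failures,
        baseline_evals=1 if variant == "dds" else config.swarm.n_particles,
    )


def aggregate_convergence(batch: TrialBatch) -> pd.DataFrame:
    """Mean/SD scaled-error curve on the common evaluation grid 1..N.

    Traces are step functions of best-so-far; each is scaled by its own
    initial best (the best after ``baseline_evals`` evaluations, so the curve
    is exactly 1.0 through initialization) and carried forward to every
    evaluation index, then the mean and SD are taken pointwise.  Invariant to
    trial ordering.
    """
    if not batch.results:
        raise ValueError("batch holds no successful trials")
    n = max(r.n_evaluations for r in batch.results)
    base = batch.baseline_evals
    curves = np.empty((len(batch.results), n))
    for i, r in enumerate(batch.results):
        best = r.best_so_far()
        scaled = best / best[base - 1]
        scaled[:base] = 1.0
        curves[i, : scaled.size] = scaled
        curves[i, scaled.size:] = scaled[-1]
    return pd.DataFrame(
        {
            "evaluation": np.arange(1, n + 1),
            "mean_scaled_error": curves.mean(axis=0),
            "sd_scaled_error": curves.std(axis=0, ddof=1) if curves.shape[0] > 1
            else np.zeros(n),
        }
    )


def batch_summary(batch: TrialBatch) -> dict:
    """Scalar summary of a batch: mean/SD of final scaled error and raw best."""
    scaled = batch.final_scaled_errors()
    finals = batch.final_values()
    return {
        "variant": batch.variant,
        "objective": batch.objective_name,
        "dimension": batch.dimension,
        "trials": batch.trials,
        "completed": len(batch.results),
        "failed": len(batch.failures),
        "mean_scaled_final_error": float(scaled.mean()),
        "sd_scaled_final_error": float(scaled.std(ddof=1)) if scaled.size > 1 else 0.0,
        "mean_final_value": float(finals.mean()),
        "best_final_value": float(finals.min()),
    }


# ---------------------------------------------------------------------------
# Result I/O
# ---------------------------------------------------------------------------

def result_to_json(result: OptimizationResult, path: str | Path) -> None:
    payload = {
        "best_vector": result.best_vector.tolist(),
        "best_value": result.best_value,
        "seed": result.seed,
        "n_evaluations": result.n_evaluations,
        "phase_log": [
            {"phase": name, "start": start, "end": end}
            for name, start, end in result.phase_log
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def trace_to_csv(result: OptimizationResult, path: str | Path) -> None:
    """Trace CSV: evaluation_index, best_value, scaled_best_value."""
    best = result.best_so_far()
    pd.DataFrame(
        {
            "evaluation_index": np.arange(1, best.size + 1),
            "best_value": best,
            "scaled_best_value": scaled_error(best),
        }
    ).to_csv(path, index=False)


def trace_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
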
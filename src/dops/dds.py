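"""Greedy dynamically dimensioned search (phase 2 of DOPS).

DDS refines a single incumbent solution.  At iteration i a random subset J of
dimensions is chosen — each dimension independently with probability P_i,
which decreases from 1 toward 0 over the phase budget, so search narrows from
global to effectively one-dimensional local moves; at least one dimension is
always perturbed.  The selected dimensions receive zero-mean normal
perturbations with per-dimension standard deviation sigma = R * (upper -
lower), R = 0.2 by default.  Candidates are reflected into the box and
accepted only on strict improvement.

Two schedules for P_i are provided.  The default ("reference") is the
original Tolson–Shoemaker form ``1 - ln(i)/ln(B)`` for a phase budget of B
iterations, which decreases from 1 at i=1 to 0 at i=B.  The alternative
("as-printed") form ``1 - log(i/B)`` is kept selectable for auditability; it
is >= 1 throughout the phase (the log of a ratio <= 1 is <= 0) and therefore
never narrows the search — see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objective import (
    BoundsBox,
    EvaluationLedger,
    ObjectiveSpec,
    evaluate_with_budget,
)
from .swarm import reflect_bounds

__all__ = [
    "PerturbationSettings",
    "DDSState",
    "perturb_probability",
    "select_dimensions",
    "dds_candidate",
    "dds_step",
]

_FORMULAS = ("reference", "as-printed")


@dataclass(frozen=True)
class PerturbationSettings:
    """Perturbation size and probability-schedule choice for DDS.

    ``r`` is the scalar perturbation size; the per-dimension standard
    deviation is ``r * (upper - lower)``.
    """

    r: float = 0.2
    probability_formula: str = "reference"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("perturbation size r must be positive")
        if self.probability_formula not in _FORMULAS:
            raise ValueError(
                f"probability_formula must be one of {_FORMULAS}"
            )

    def sigma(self, bounds: BoundsBox) -> np.ndarray:
        return self.r * bounds.width


@dataclass
class DDSState:
    """Incumbent solution and iteration counter of a DDS phase."""

    incumbent: np.ndarray
    incumbent_value: float
    iteration: int  # i, starts at 1 on phase entry
    total_dds_budget: int  # iterations available to this phase


def perturb_probability(
    i: int, dds_budget: int, formula: str = "reference"
) -> float:
    """Probability that each dimension is perturbed at iteration ``i``.

    The "reference" schedule is ``1 - ln(i)/ln(dds_budget)``: 1.0 at the
    first iteration, 0.0 at the last, monotone non-increasing.  The
    "as-printed" schedule ``1 - ln(i/dds_budget)`` is clipped into [0, 1].
    """
    if dds_budget < 2:
        raise ValueError("dds_budget must be >= 2")
    if not 1 <= i <= dds_budget:
        raise ValueError(f"iteration {i} outside [1, {dds_budget}]")
    if formula == "reference":
        p = 1.0 - np.log(i) / np.log(dds_budget)
    elif formula == "as-printed":
        p = 1.0 - np.log(i / dds_budget)
    else:
        raise ValueError(f"unknown probability formula {formula!r}")
    return float(min(1.0, max(0.0, p)))


def select_dimensions(
    p_include: float, dimension: int, rng: np.random.Generator
) -> np.ndarray:
    """Choose the index set J: each dimension independently with probability ``p_include``.

    If the draw leaves J empty, one dimension is chosen uniformly at random,
    so at least one dimension is always perturbed.
    """
    if not 0.0 <= p_include <= 1.0:
        raise ValueError("inclusion probability must lie in [0, 1]")
    mask = rng.uniform(size=dimension) < p_include
    selected = np.flatnonzero(mask)
    if selected.size == 0:
        selected = np.array([rng.integers(dimension)])
    return selected


def dds_candidate(
    state: DDSState,
    selected: np.ndarray,
    settings: PerturbationSettings,
    bounds: BoundsBox,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb the incumbent on the selected dimensions and reflect into the box."""
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected dimension set must be non-empty")
    sigma = settings.sigma(bounds)
    candidate = state.incumbent.copy()
    candidate[selected] += rng.normal(size=selected.size) * sigma[selected]
    return reflect_bounds(candidate, bounds)


def dds_step(
    state: DDSState,
    spec: ObjectiveSpec,
    ledger: EvaluationLedger,
    settings: PerturbationSettings,
    rng: np.random.Generator,
) -> DDSState:
    """One DDS iteration: propose, evaluate (1 budget unit), accept greedily.

    The incumbent is replaced only on strict improvement; the iteration
    counter advances regardless.
    """
    p = perturb_probability(
        state.iteration, state.total_dds_budget, settings.probability_formula
    )
    selected = select_dimensions(p, spec.dimension, rng)
    candidate = dds_candidate(state, selected, settings, spec.bounds, rng)
    value = evaluate_with_budget(spec, candidate, ledger)
    if value < state.incumbent_value:
        state.incumbent = candidate
        state.incumbent_value = value
    state.iteration += 1
    return state
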
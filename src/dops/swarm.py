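"""Velocity-free multi-swarm particle swarm search (phase 1 of DOPS).

NP particles are partitioned uniformly at random into k equal sub-swarms.
Each particle moves under a velocity-free update: the new position is a
weighted combination of its current position (weight theta1, the position
"inertia", scheduled linearly from w_max down to w_min across the evaluation
budget), its personal best and its sub-swarm best (weights theta2, theta3,
each damped by a fresh uniform random vector).  Bounds are enforced by
reflection.  Every ``regroup_interval`` iterations the particles are randomly
redistributed across sub-swarms, which keeps the sub-populations mixing.
Search stagnation — the global best improving by at most a relative tolerance
for a run of consecutive iterations — is the signal on which the controller
switches to the refinement phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objective import (
    BoundsBox,
    EvaluationLedger,
    ObjectiveSpec,
    evaluate_with_budget,
)

__all__ = [
    "SwarmSettings",
    "Particle",
    "SubSwarm",
    "SwarmState",
    "BudgetError",
    "inertia_weight",
    "reflect_bounds",
    "update_particle",
    "initialize_swarm",
    "swarm_iteration",
    "regroup",
    "detect_stagnation",
]


@dataclass(frozen=True)
class SwarmSettings:
    """Tunables of the swarm phase.

    Defaults follow the reference study conditions: 40 particles in 5
    sub-swarms, inertia scheduled 0.9 -> 0.4, social/cognitive weights 1.5,
    regrouping every 10 iterations, stagnation declared after 4 consecutive
    iterations with under 1% relative improvement of the global best.
    """

    n_particles: int = 40
    n_subswarms: int = 5
    w_max: float = 0.9
    w_min: float = 0.4
    theta2: float = 1.5
    theta3: float = 1.5
    regroup_interval: int = 10
    stagnation_tolerance: float = 0.01
    stagnation_limit: int = 4

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_subswarms < 1:
            raise ValueError("particle and sub-swarm counts must be positive")
        if self.n_particles % self.n_subswarms != 0:
            raise ValueError(
                f"n_particles={self.n_particles} must be divisible by "
                f"n_subswarms={self.n_subswarms}"
            )
        if not (0.0 < self.w_min < self.w_max):
            raise ValueError("require 0 < w_min < w_max")
        if self.theta2 <= 0 or self.theta3 <= 0:
            raise ValueError("theta2 and theta3 must be positive")
        if self.regroup_interval < 1:
            raise ValueError("regroup_interval must be >= 1")


@dataclass
class Particle:
    """A candidate parameter vector with greedy personal-best memory."""

    position: np.ndarray
    personal_best: np.ndarray
    personal_best_value: float


@dataclass
class SubSwarm:
    """A group of particle indices with its cached group best."""

    members: list[int]
    swarm_best: np.ndarray
    swarm_best_value: float


@dataclass
class SwarmState:
    """Full state of the multi-swarm search."""

    particles: list[Particle]
    subswarms: list[SubSwarm]
    iteration: int
    global_best: np.ndarray
    global_best_value: float
    best_history: list[float] = field(default_factory=list)

    @property
    def stagnated(self) -> bool:
        return detect_stagnation(self.best_history)


def inertia_weight(j: int, total_budget: int, w_max: float = 0.9, w_min: float = 0.4) -> float:
    """Linearly decreasing inertia: w_max at j=1 down to w_min at j=N.

    ``j`` is indexed in function evaluations so the schedule spans the whole
    budget regardless of how the evaluations split across phases.
    """
    if total_budget < 2:
        raise ValueError("total_budget must be >= 2 for a linear schedule")
    j = min(max(j, 1), total_budget)
    return (total_budget - j) * (w_max - w_min) / (total_budget - 1) + w_min


def reflect_bounds(x: np.ndarray, bounds: BoundsBox) -> np.ndarray:
    """Fold an out-of-box point back inside by reflection at the violated bound.

    A single reflection is applied per dimension; if the overshoot is wider
    than the box so the reflected value still violates the opposite side, the
    value is clamped to the bound that was violated first.  In-bounds
    dimensions are returned unchanged.
    """
    x = np.asarray(x, dtype=float).copy()
    lo, hi = bounds.lower, bounds.upper
    over = x > hi
    x[over] = hi[over] - (x[over] - hi[over])
    under = ~over & (x < lo)
    x[under] = lo[under] + (lo[under] - x[under])
    # overshoot wider than the box: clamp to the bound violated first
    x[over] = np.where(x[over] < lo[over], hi[over], x[over])
    x[under] = np.where(x[under] > hi[under], lo[under], x[under])
    return x


def update_particle(
    particle: Particle,
    swarm_best: np.ndarray,
    theta1: float,
    settings: SwarmSettings,
    rng: np.random.Generator,
) -> np.ndarray:
    """Propose a new position for one particle (velocity-free update).

    Returns ``theta1*z + theta2*r1*(L - z) + theta3*r2*(G_k - z)`` with r1, r2
    fresh uniform(0,1) vectors; the caller applies reflection and evaluates.
    """
    z = particle.position
    if swarm_best.shape != z.shape:
        raise ValueError("dimension mismatch between particle and swarm best")
    r1 = rng.uniform(size=z.shape)
    r2 = rng.uniform(size=z.shape)
    return (
        theta1 * z
        + settings.theta2 * r1 * (particle.personal_best - z)
        + settings.theta3 * r2 * (swarm_best - z)
    )


def _partition(indices: np.ndarray, k: int, rng: np.random.Generator) -> list[list[int]]:
    perm = rng.permutation(indices)
    return [list(map(int, chunk)) for chunk in np.split(perm, k)]


def _subswarm_from_members(members: list[int], particles: list[Particle]) -> SubSwarm:
    best_idx = min(members, key=lambda i: particles[i].personal_best_value)
    best = particles[best_idx]
    return SubSwarm(
        members=members,
        swarm_best=best.personal_best.copy(),
        swarm_best_value=best.personal_best_value,
    )


def _refresh_global(state: SwarmState) -> None:
    best = min(state.subswarms, key=lambda s: s.swarm_best_value)
    if best.swarm_best_value < state.global_best_value:
        state.global_best = best.swarm_best.copy()
        state.global_best_value = best.swarm_best_value


class BudgetError(RuntimeError):
    """Raised when a whole-iteration operation cannot be afforded."""


def initialize_swarm(
    spec: ObjectiveSpec,
    settings: SwarmSettings,
    ledger: EvaluationLedger,
    rng: np.random.Generator,
    seed_position: np.ndarray | None = None,
    seed_value: float | None = None,
) -> SwarmState:
    """Draw NP uniform positions, evaluate each, and group into k sub-swarms.

    ``seed_position``/``seed_value`` optionally inject one particle with a
    known (already evaluated) solution — used when a swarm phase restarts
    from a refinement incumbent; that particle costs no evaluation.
    """
    np_count = settings.n_particles
    fresh = np_count if seed_position is None else np_count - 1
    if ledger.remaining < fresh:
        raise BudgetError(
            f"initialization needs {fresh} evaluations, only {ledger.remaining} remain"
        )
    positions = spec.bounds.sample(rng, fresh)
    particles: list[Particle] = []
    if seed_position is not None:
        if seed_value is None:
            raise ValueError("seed_value required with seed_position")
        particles.append(
            Particle(
                position=np.asarray(seed_position, dtype=float).copy(),
                personal_best=np.asarray(seed_position, dtype=float).copy(),
                personal_best_value=float(seed_value),
            )
        )
    for pos in positions:
        value = evaluate_with_budget(spec, pos, ledger)
        particles.append(
            Particle(position=pos.copy(), personal_best=pos.copy(), personal_best_value=value)
        )
    membership = _partition(np.arange(np_count), settings.n_subswarms, rng)
    subswarms = [_subswarm_from_members(m, particles) for m in membership]
    best = min(subswarms, key=lambda s: s.swarm_best_value)
    state = SwarmState(
        particles=particles,
        subswarms=subswarms,
        iteration=0,
        global_best=best.swarm_best.copy(),
        global_best_value=best.swarm_best_value,
    )
    return state


def swarm_iteration(
    state: SwarmState,
    spec: ObjectiveSpec,
    settings: SwarmSettings,
    ledger: EvaluationLedger,
    rng: np.random.Generator,
    total_budget: int | None = None,
) -> SwarmState:
    """Advance the swarm by one full iteration (NP evaluations).

    Partial iterations are never performed: raises :class:`BudgetError` if
    fewer than NP evaluations remain.  Personal bests update greedily
    (strict improvement only); sub-swarm and global bests are refreshed.
    """
    if ledger.remaining < settings.n_particles:
        raise BudgetError(
            f"iteration needs {settings.n_particles} evaluations, "
            f"only {ledger.remaining} remain"
        )
    n = total_budget if total_budget is not None else ledger.budget
    theta1 = inertia_weight(ledger.consumed, n, settings.w_max, settings.w_min)
    for sub in state.subswarms:
        for i in sub.members:
            p = state.particles[i]
            proposal = update_particle(p, sub.swarm_best, theta1, settings, rng)
            proposal = reflect_bounds(proposal, spec.bounds)
            value = evaluate_with_budget(spec, proposal, ledger)
            p.position = proposal
            if value < p.personal_best_value:
                p.personal_best = proposal.copy()
                p.personal_best_value = value
    for idx, sub in enumerate(state.subswarms):
        state.subswarms[idx] = _subswarm_from_members(sub.members, state.particles)
    _refresh_global(state)
    state.iteration += 1
    state.best_history.append(state.global_best_value)
    return state


def regroup(state: SwarmState, rng: np.random.Generator) -> SwarmState:
    """Randomly re-partition particles into equal sub-swarms.

    Personal bests are retained; sub-swarm bests are recomputed from the new
    membership; the global best is unchanged.
    """
    k = len(state.subswarms)
    n = len(state.particles)
    membership = _partition(np.arange(n), k, rng)
    state.subswarms = [_subswarm_from_members(m, state.particles) for m in membership]
    return state


def detect_stagnation(
    recent: list[float] | np.ndarray,
    tolerance: float = 0.01,
    limit: int = 4,
) -> bool:
    """True iff each of the last ``limit`` steps improved by at most ``tolerance`` (relative).

    Needs ``limit + 1`` history entries to form ``limit`` consecutive steps;
    with fewer, returns False.
    """
    recent = np.asarray(recent, dtype=float)
    if recent.size < limit + 1:
        return False
    window = recent[-(limit + 1):]
    prev, cur = window[:-1], window[1:]
    denom = np.where(np.abs(prev) > 0, np.abs(prev), 1.0)
    rel = np.abs(prev - cur) / denom
    return bool(np.all(rel <= tolerance))
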
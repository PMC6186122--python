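"""Orchestration of the hybrid search and its ablation baselines.

DOPS spends an initial fraction of the evaluation budget on the multi-swarm
particle phase, monitors the global best for stagnation, and on stagnation
(or on hitting a configurable phase-1 cap) hands the best particle to the
greedy dynamically dimensioned search, which consumes the remaining budget.
The swarm fraction F is not preset: it is whatever fraction (NP * iterations
+ initialization) / N the swarm actually consumed before the switch.

Variants:

``run_dops``
    The two-phase hybrid (one switch).
``run_msdops``
    Multi-switch variant: whenever the DDS phase drives the objective to a
    fraction (default 90%) of its phase-entry value, control returns to a
    fresh swarm phase seeded with the DDS incumbent.
``run_mspso_only``
    Multi-swarm particle phase for the whole budget (ablation baseline).
``run_dds_only``
    DDS from a uniform random point for the whole budget (ablation baseline).

All variants consume exactly N evaluations, produce monotone best-so-far
traces, and are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dds import DDSState, PerturbationSettings, dds_step
from .objective import EvaluationLedger, ObjectiveSpec, evaluate_with_budget
from .swarm import (
    SwarmSettings,
    detect_stagnation,
    initialize_swarm,
    regroup,
    swarm_iteration,
)

__all__ = [
    "DOPSConfig",
    "OptimizationResult",
    "run_dops",
    "run_msdops",
    "run_mspso_only",
    "run_dds_only",
    "run_variant",
    "VARIANTS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DOPSConfig:
    """Complete configuration of a single optimization run."""

    total_budget: int = 4000
    swarm: SwarmSettings = field(default_factory=SwarmSettings)
    dds: PerturbationSettings = field(default_factory=PerturbationSettings)
    multiswitch: bool = False
    switchback_ratio: float = 0.9
    phase1_cap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_budget < self.swarm.n_particles:
            raise ValueError(
                "total_budget must cover at least one swarm initialization "
                f"({self.swarm.n_particles} evaluations)"
            )
        if not 0.0 <= self.switchback_ratio < 1.0:
            raise ValueError("switchback_ratio must lie in [0, 1)")
        if not 0.0 < self.phase1_cap_fraction <= 1.0:
            raise ValueError("phase1_cap_fraction must lie in (0, 1]")


@dataclass
class OptimizationResult:
    """Outcome of one optimization run.

    ``phase_log`` holds ``(phase name, first evaluation index, last
    evaluation index)`` triples that partition [1, consumed].
    """

    best_vector: np.ndarray
    best_value: float
    trace: list[tuple[int, float]]
    phase_log: list[tuple[str, int, int]]
    seed: int

    @property
    def n_evaluations(self) -> int:
        return len(self.trace)

    def best_so_far(self) -> np.ndarray:
        return np.array([v for _, v in self.trace], dtype=float)


def _close_phase(
    phase_log: list[tuple[str, int, int]], name: str, start: int, end: int
) -> None:
    if end >= start:
        phase_log.append((name, start, end))


def _swarm_phase(
    spec: ObjectiveSpec,
    config: DOPSConfig,
    ledger: EvaluationLedger,
    rng: np.random.Generator,
    *,
    phase_cap_evals: int,
    seed_position: np.ndarray | None = None,
    seed_value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Run one swarm phase (init + iterations) until stagnation, cap, or budget.

    Returns the phase's global best.  ``phase_cap_evals`` caps the
    evaluations this phase may consume (counted from its start).
    """
    settings = config.swarm
    start_consumed = ledger.consumed
    state = initialize_swarm(
        spec, settings, ledger, rng, seed_position=seed_position, seed_value=seed_value
    )
    while True:
        used = ledger.consumed - start_consumed
        if ledger.remaining < settings.n_particles:
            break
        if used + settings.n_particles > phase_cap_evals:
            break
        swarm_iteration(
            state, spec, settings, ledger, rng, total_budget=config.total_budget
        )
        if state.iteration % settings.regroup_interval == 0:
            regroup(state, rng)
        if detect_stagnation(
            state.best_history,
            settings.stagnation_tolerance,
            settings.stagnation_limit,
        ):
            logger.info(
                "swarm phase stagnated after %d iterations (%d evaluations)",
                state.iteration,
                ledger.consumed - start_consumed,
            )
            break
    return state.global_best, state.global_best_value


def _dds_phase(
    spec: ObjectiveSpec,
    config: DOPSConfig,
    ledger: EvaluationLedger,
    rng: np.random.Generator,
    incumbent: np.ndarray,
    incumbent_value: float,
    *,
    allow_switchback: bool,
) -> tuple[np.ndarray, float, bool]:
    """Run DDS until the budget ends or (optionally) the switch-back fires.

    Returns ``(incumbent, value, switched_back)``.  The iteration horizon is
    the remaining budget at phase entry.
    """
    horizon = max(ledger.remaining, 2)
    state = DDSState(
        incumbent=np.asarray(incumbent, dtype=float).copy(),
        incumbent_value=float(incumbent_value),
        iteration=1,
        total_dds_budget=horizon,
    )
    entry_value = state.incumbent_value
    # For a positive entry value this is the plain "reduced to
    # switchback_ratio of its entry value" rule; stated as a required
    # improvement of (1 - ratio)*|entry| so it extends to objectives that
    # go negative (where a fixed fraction of the entry value is already met
    # at entry).
    threshold = entry_value - (1.0 - config.switchback_ratio) * abs(entry_value)
    while ledger.remaining > 0:
        dds_step(state, spec, ledger, config.dds, rng)
        if (
            allow_switchback
            and state.incumbent_value < entry_value
            and state.incumbent_value <= threshold
            and ledger.remaining >= config.swarm.n_particles
        ):
            logger.info(
                "DDS reached %.3g (<= %.0f%% of entry %.3g); switching back to swarm",
                state.incumbent_value,
                100 * config.switchback_ratio,
                entry_value,
            )
            return state.incumbent, state.incumbent_value, True
    return state.incumbent, state.incumbent_value, False


def _finalize(
    ledger: EvaluationLedger,
    phase_log: list[tuple[str, int, int]],
    best_vector: np.ndarray,
    seed: int,
) -> OptimizationResult:
    return OptimizationResult(
        best_vector=np.asarray(best_vector, dtype=float).copy(),
        best_value=ledger.best_value,
        trace=list(ledger.trace),
        phase_log=phase_log,
        seed=seed,
    )


def _run_hybrid(spec: ObjectiveSpec, config: DOPSConfig) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    ledger = EvaluationLedger(config.total_budget)
    phase_log: list[tuple[str, int, int]] = []
    cap = int(np.floor(config.phase1_cap_fraction * config.total_budget))
    cap = max(cap, config.swarm.n_particles)

    start = ledger.consumed + 1
    best, best_value = _swarm_phase(spec, config, ledger, rng, phase_cap_evals=cap)
    _close_phase(phase_log, "swarm", start, ledger.consumed)

    while ledger.remaining > 0:
        start = ledger.consumed + 1
        best, best_value, switched = _dds_phase(
            spec,
            config,
            ledger,
            rng,
            best,
            best_value,
            allow_switchback=config.multiswitch,
        )
        _close_phase(phase_log, "dds", start, ledger.consumed)
        if not switched:
            break
        start = ledger.consumed + 1
        # later swarm phases are capped only by the remaining budget
        best, best_value = _swarm_phase(
            spec,
            config,
            ledger,
            rng,
            phase_cap_evals=max(
                config.swarm.n_particles,
                int(np.floor(config.phase1_cap_fraction * ledger.remaining)),
            ),
            seed_position=best,
            seed_value=best_value,
        )
        _close_phase(phase_log, "swarm", start, ledger.consumed)
    return _finalize(ledger, phase_log, best, config.seed)


def run_dops(spec: ObjectiveSpec, config: DOPSConfig) -> OptimizationResult:
    """Two-phase hybrid: swarm until stagnation/cap, then DDS to the budget."""
    if config.multiswitch:
        config = replace(config, multiswitch=False)
    return _run_hybrid(spec, config)


def run_msdops(spec: ObjectiveSpec, config: DOPSConfig) -> OptimizationResult:
    """Multi-switch hybrid: DDS hands control back to a fresh swarm whenever
    it reduces the objective to ``switchback_ratio`` of its phase-entry value."""
    if not config.multiswitch:
        config = replace(config, multiswitch=True)
    return _run_hybrid(spec, config)


def run_mspso_only(spec: ObjectiveSpec, config: DOPSConfig) -> OptimizationResult:
    """Ablation baseline: multi-swarm particle phase for the entire budget."""
    rng = np.random.default_rng(config.seed)
    ledger = EvaluationLedger(config.total_budget)
    settings = config.swarm
    state = initialize_swarm(spec, settings, ledger, rng)
    while ledger.remaining >= settings.n_particles:
        swarm_iteration(
            state, spec, settings, ledger, rng, total_budget=config.total_budget
        )
        if state.iteration % settings.regroup_interval == 0:
            regroup(state, rng)
    # spend any sub-iteration remainder on fresh uniform samples so every
    # variant consumes exactly N evaluations
    while ledger.remaining > 0:
        x = spec.bounds.sample(rng, 1)[0]
        value = evaluate_with_budget(spec, x, ledger)
        if value < state.global_best_value:
            state.global_best = x.copy()
            state.global_best_value = value
    phase_log = [("swarm", 1, ledger.consumed)]
    return _finalize(ledger, phase_log, state.global_best, config.seed)


def run_dds_only(spec: ObjectiveSpec, config: DOPSConfig) -> OptimizationResult:
    """Ablation baseline: DDS from a uniform random point for the whole budget."""
    rng = np.random.default_rng(config.seed)
    ledger = EvaluationLedger(config.total_budget)
    x0 = spec.bounds.sample(rng, 1)[0]
    value = evaluate_with_budget(spec, x0, ledger)
    state = DDSState(
        incumbent=x0.copy(),
        incumbent_value=value,
        iteration=1,
        total_dds_budget=max(ledger.remaining, 2),
    )
    while ledger.remaining > 0:
        dds_step(state, spec, ledger, config.dds, rng)
    phase_log = [("dds", 1, ledger.consumed)]
    return _finalize(ledger, phase_log, state.incumbent, config.seed)


VARIANTS = {
    "dops": run_dops,
    "msdops": run_msdops,
    "mspso": run_mspso_only,
    "dds": run_dds_only,
}


def run_variant(
    variant: str, spec: ObjectiveSpec, config: DOPSConfig
) -> OptimizationResult:
    """Dispatch by variant name ("dops" | "msdops" | "mspso" | "dds")."""
    try:
        runner = VARIANTS[variant]
    except KeyError:
        raise KeyError(
            f"unknown variant {variant!r}; available: {sorted(VARIANTS)}"
        ) from None
    return runner(spec, config)
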
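"""Desk-scale biochemical parameter-estimation problem.

A small mass-action reaction network is integrated as an ODE system; noisy
time-course observations of a subset of species are generated at known
nominal rate constants, and the estimation objective is the sum of squared
residuals between simulated and observed trajectories, summed unweighted
over experiments.  Recovering the nominal rate constants from this synthetic
data, within multiplicative bounds around them, is the standard validation
protocol for a parameter-estimation method.

The bundled demo network is a 6-species, 8-reaction activation cascade with
the initiation / amplification / inhibition architecture typical of protease
networks such as coagulation: a decaying trigger activates an enzyme, the
active enzyme activates a second zymogen, the second active species feeds
back positively on the first activation and induces an inhibitor that
neutralizes both active species.  Two training experiments differ in the
initial trigger dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .controller import DOPSConfig, run_dops
from .objective import BoundsBox, ObjectiveSpec

__all__ = [
    "MassActionModel",
    "ExperimentDataset",
    "SSEObjective",
    "IntegrationFailure",
    "simulate",
    "generate_synthetic_data",
    "sse_objective",
    "build_sse_spec",
    "demo_model",
    "demo_datasets",
    "demo_objective",
    "recovery_experiment",
    "dataset_to_csv",
    "dataset_from_csv",
]


class IntegrationFailure(RuntimeError):
    """ODE integration failed; carries the offending parameter vector."""

    def __init__(self, message: str, p: np.ndarray):
        super().__init__(message)
        self.p = np.asarray(p, dtype=float)


@dataclass(frozen=True)
class MassActionModel:
    """A reaction network with mass-action kinetics.

    Each reaction r fires at rate ``p[r] * prod(x[reactants[r]])`` (reactant
    indices listed with multiplicity); the state derivative is the
    stoichiometry matrix times the rate vector.

    Parameters
    ----------
    species_names
        Identifiers for the n state variables.
    reactants
        Per reaction, the species indices entering the rate law.
    stoichiometry
        Matrix of shape (n_species, n_reactions): net change of each species
        per firing of each reaction.
    rate_constants
        Nominal rate constants p_nom (the estimation target), all >= 0.
    initial_state
        Default initial concentrations x_0, all >= 0.
    """

    species_names: tuple[str, ...]
    reactants: tuple[tuple[int, ...], ...]
    stoichiometry: np.ndarray
    rate_constants: np.ndarray
    initial_state: np.ndarray

    def __post_init__(self) -> None:
        stoich = np.asarray(self.stoichiometry, dtype=float)
        p = np.asarray(self.rate_constants, dtype=float)
        x0 = np.asarray(self.initial_state, dtype=float)
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "rate_constants", p)
        object.__setattr__(self, "initial_state", x0)
        n_sp, n_rx = stoich.shape
        if len(self.species_names) != n_sp or x0.size != n_sp:
            raise ValueError("species_names, stoichiometry, initial_state disagree")
        if len(self.reactants) != n_rx or p.size != n_rx:
            raise ValueError("reactants, stoichiometry, rate_constants disagree")
        if np.any(p < 0) or np.any(x0 < 0):
            raise ValueError("rate constants and initial concentrations must be >= 0")

    @property
    def n_species(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    def _rate_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        # mass-action orders here are at most 2; pad unimolecular reactions
        # with a sentinel that multiplies by 1
        if not hasattr(self, "_idx_cache"):
            order = max((len(r) for r in self.reactants), default=0)
            idx = np.zeros((order, self.n_reactions), dtype=int)
            mask = np.zeros((order, self.n_reactions))
            for r, species in enumerate(self.reactants):
                for level, i in enumerate(species):
                    idx[level, r] = i
                    mask[level, r] = 1.0
            object.__setattr__(self, "_idx_cache", (idx, mask))
        return self._idx_cache

    def rhs(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        idx, mask = self._rate_index_arrays()
        factors = np.where(mask > 0, x[idx], 1.0)
        rates = p * factors.prod(axis=0)
        return self.stoichiometry @ rates

    # -- JSON round-trip ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_names": list(self.species_names),
            "reactants": [list(r) for r in self.reactants],
            "stoichiometry": self.stoichiometry.tolist(),
            "rate_constants": self.rate_constants.tolist(),
            "initial_state": self.initial_state.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MassActionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            species_names=tuple(payload["species_names"]),
            reactants=tuple(tuple(r) for r in payload["reactants"]),
            stoichiometry=np.asarray(payload["stoichiometry"], dtype=float),
            rate_constants=np.asarray(payload["rate_constants"], dtype=float),
            initial_state=np.asarray(payload["initial_state"], dtype=float),
        )


@dataclass
class ExperimentDataset:
    """Noisy time-course observations of a subset of species.

    ``initial_state`` overrides the model default so experiments can differ
    in, e.g., the trigger dose.
    """

    times: np.ndarray
    observed_species: tuple[int, ...]
    measurements: np.ndarray
    noise_sd: float = 0.0
    initial_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.measurements = np.asarray(self.measurements, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        expected = (self.times.size, len(self.observed_species))
        if self.measurements.shape != expected:
            raise ValueError(
                f"measurements shape {self.measurements.shape} != {expected}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate(
    model: MassActionModel,
    p: np.ndarray,
    times: np.ndarray,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate the network at rate constants ``p``; rows are the requested times.

    The first requested time is taken as t_0, at which the state equals x_0
    exactly.  Raises :class:`IntegrationFailure` if the stiff integrator does
    not converge.
    """
    p = np.asarray(p, dtype=float)
    times = np.asarray(times, dtype=float)
    x0 = model.initial_state if initial_state is None else np.asarray(initial_state, float)

    def f(x: np.ndarray, _t: float) -> np.ndarray:
        return model.rhs(x, p)

    import warnings
    from scipy.integrate import ODEintWarning

    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        traj, info = odeint(
            f,
            x0,
            times,
            rtol=1e-7,
            atol=1e-9,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(traj)):
        raise IntegrationFailure(f"ODE integration failed: {info['message']}", p)
    traj[0] = x0
    return traj


def generate_synthetic_data(
    model: MassActionModel,
    p_nom: np.ndarray,
    times: np.ndarray,
    observed_species: tuple[int, ...],
    noise_sd: float,
    rng: np.random.Generator,
    initial_state: np.ndarray | None = None,
) -> ExperimentDataset:
    """Simulate at nominal parameters and add i.i.d. zero-mean Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traj = simulate(model, p_nom, times, initial_state=initial_state)
    clean = traj[:, list(observed_species)]
    noise = rng.normal(scale=noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    return ExperimentDataset(
        times=times,
        observed_species=tuple(observed_species),
        measurements=clean + noise,
        noise_sd=noise_sd,
        initial_state=initial_state,
    )


@dataclass
class SSEObjective:
    """Sum-of-squared-error objective over one or more experiments.

    Integration failures inside the search box return a large sentinel value
    instead of raising, so the optimizer's budget accounting stays intact.
    """

    model: MassActionModel
    datasets: list[ExperimentDataset]
    bounds: BoundsBox
    nominal: np.ndarray
    sentinel: float = 1e12
    failures: list[np.ndarray] = field(default_factory=list)

    def __call__(self, p: np.ndarray) -> float:
        return sse_objective(self, p)


def sse_objective(obj: SSEObjective, p: np.ndarray) -> float:
    """Unweighted sum over datasets, times and observed species of squared residuals."""
    total = 0.0
    for ds in obj.datasets:
        try:
            traj = simulate(obj.model, p, ds.times, initial_state=ds.initial_state)
        except IntegrationFailure:
            obj.failures.append(np.asarray(p, dtype=float).copy())
            return obj.sentinel
        residuals = traj[:, list(ds.observed_species)] - ds.measurements
        total += float(np.sum(residuals**2))
    return total


def build_sse_spec(
    model: MassActionModel,
    datasets: list[ExperimentDataset],
    lower_factor: float = 0.2,
    upper_factor: float = 5.0,
    name: str = "sse",
) -> tuple[ObjectiveSpec, SSEObjective]:
    """Wrap an SSE objective as a bounded :class:`ObjectiveSpec`.

    The search box is multiplicative around the nominal rate constants:
    ``lower_factor * p_nom`` to ``upper_factor * p_nom`` per dimension.
    """
    p_nom = model.rate_constants
    bounds = BoundsBox(lower_factor * p_nom, upper_factor * p_nom)
    obj = SSEObjective(model=model, datasets=datasets, bounds=bounds, nominal=p_nom.copy())
    spec = ObjectiveSpec(name=name, evaluate=obj, bounds=bounds)
    return spec, obj


# ---------------------------------------------------------------------------
# Bundled demo fixture
# ---------------------------------------------------------------------------

def demo_model() -> MassActionModel:
    """The bundled 6-species, 8-reaction activation cascade.

    Species: TR (trigger), E / Ea (zymogen and active enzyme), Z / Za
    (second zymogen and its active form), I (inhibitor).

    Reactions (mass action; k in 1/(conc·time) for bimolecular, 1/time else):

    ==  =======================  ==========================================
    r0  TR + E  -> TR + Ea       trigger-driven initiation
    r1  Ea + Z  -> Ea + Za       amplification
    r2  Za + E  -> Za + Ea       positive feedback
    r3  Za      -> Za + I        inhibitor induction (negative feedback)
    r4  I + Ea  -> (consumed)    inhibition of Ea
    r5  I + Za  -> (consumed)    inhibition of Za
    r6  TR      -> (decay)       trigger decay
    r7  Za      -> (clearance)   clearance of Za
    ==  =======================  ==========================================
    """
    names = ("TR", "E", "Ea", "Z", "Za", "I")
    TR, E, Ea, Z, Za, I = range(6)
    reactants = ((TR, E), (Ea, Z), (Za, E), (Za,), (I, Ea), (I, Za), (TR,), (Za,))
    stoich = np.zeros((6, 8))
    stoich[E, 0], stoich[Ea, 0] = -1, +1
    stoich[Z, 1], stoich[Za, 1] = -1, +1
    stoich[E, 2], stoich[Ea, 2] = -1, +1
    stoich[I, 3] = +1
    stoich[I, 4], stoich[Ea, 4] = -1, -1
    stoich[I, 5], stoich[Za, 5] = -1, -1
    stoich[TR, 6] = -1
    stoich[Za, 7] = -1
    p_nom = np.array([0.15, 0.20, 0.05, 0.30, 0.10, 0.08, 0.25, 0.10])
    x0 = np.array([1.0, 10.0, 0.0, 10.0, 0.0, 0.0])
    return MassActionModel(
        species_names=names,
        reactants=reactants,
        stoichiometry=stoich,
        rate_constants=p_nom,
        initial_state=x0,
    )


#: observed species in the demo: the two active enzymes
DEMO_OBSERVED = (2, 4)
#: sampling grid: 20 points over 10 time units
DEMO_TIMES = np.linspace(0.0, 10.0, 20)
#: trigger doses of the two training experiments
DEMO_TRIGGER_DOSES = (1.0, 0.25)


def demo_datasets(
    noise_sd: float = 0.0, seed: int = 0
) -> tuple[MassActionModel, list[ExperimentDataset]]:
    """Generate the two training experiments at the nominal rate constants."""
    model = demo_model()
    rng = np.random.default_rng(seed)
    datasets = []
    for dose in DEMO_TRIGGER_DOSES:
        x0 = model.initial_state.copy()
        x0[0] = dose
        datasets.append(
            generate_synthetic_data(
                model,
                model.rate_constants,
                DEMO_TIMES,
                DEMO_OBSERVED,
                noise_sd,
                rng,
                initial_state=x0,
            )
        )
    return model, datasets


def demo_objective(
    noise_sd: float = 0.0, seed: int = 0
) -> tuple[ObjectiveSpec, SSEObjective]:
    """The bundled 8-parameter estimation problem as a bounded objective."""
    model, datasets = demo_datasets(noise_sd=noise_sd, seed=seed)
    return build_sse_spec(model, datasets, name="biochem-demo")


def recovery_experiment(
    config: DOPSConfig | None = None,
    noise_sd: float = 0.0,
    trials: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery protocol on the bundled demo problem.

    Runs DOPS per trial against the SSE objective (bounds 0.2-5x nominal) and
    reports, per trial, the final best SSE, the final scaled error (final
    best divided by that trial's initial best) and the relative parameter
    error ``||p_hat - p_nom|| / ||p_nom||``.
    """
    if config is None:
        config = DOPSConfig()
    from .harness import derive_trial_seeds

    spec, obj = demo_objective(noise_sd=noise_sd, seed=base_seed)
    seeds = derive_trial_seeds(base_seed, trials)
    rows = []
    from dataclasses import replace

    for t, seed in enumerate(seeds):
        result = run_dops(spec, replace(config, seed=int(seed)))
        best = result.best_so_far()
        # initial best = best among the randomly initialized particles
        initial = best[config.swarm.n_particles - 1]
        rel_err = float(
            np.linalg.norm(result.best_vector - obj.nominal)
            / np.linalg.norm(obj.nominal)
        )
        rows.append(
            {
                "trial": t,
                "seed": int(seed),
                "initial_best": initial,
                "final_best": best[-1],
                "scaled_error": best[-1] / initial,
                "param_rel_error": rel_err,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset CSV I/O
# ---------------------------------------------------------------------------

def dataset_to_csv(
    dataset: ExperimentDataset, model: MassActionModel, path: str | Path
) -> None:
    """Write a dataset as CSV: columns ``time`` then one per observed species."""
    cols = {"time": dataset.times}
    for j, idx in enumerate(dataset.observed_species):
        cols[model.species_names[idx]] = dataset.measurements[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def dataset_from_csv(
    path: str | Path,
    model: MassActionModel,
    noise_sd: float = 0.0,
    initial_state: np.ndarray | None = None,
) -> ExperimentDataset:
    """Read a dataset written by :func:`dataset_to_csv`."""
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time"]
    observed = tuple(model.species_names.index(n) for n in names)
    return ExperimentDataset(
        times=df["time"].to_numpy(),
        observed_species=observed,
        measurements=df[names].to_numpy(),
        noise_sd=noise_sd,
        initial_state=initial_state,
    )
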
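# Methods

## Problem statement

`dops` addresses bound-constrained minimization of a deterministic black-box
objective `K(p)`, `p^L <= p <= p^U`, under a hard budget of `N` objective
evaluations.  The motivating application is kinetic-model calibration: `K`
is a sum of squared residuals between simulated and measured species time
courses, each evaluation is an ODE integration, and the evaluation count is
the only meaningful cost unit.  All claims made by this package — traces,
convergence curves, scaled errors — are stated per evaluation, enforced by
a single accounting object (`EvaluationLedger`) through which every
objective call passes.  General nonlinear constraints are out of scope;
only box bounds are supported.

## The hybrid search

### Swarm phase

`NP` particles are initialized uniformly in the box (costing `NP`
evaluations) and partitioned uniformly at random into `k` equal sub-swarms
(`NP` must be divisible by `k`).  The update rule is velocity-free: a
particle's next position is a weighted combination of its current position
(weight `theta1`), its personal best (weight `theta2 .* r1`) and its
sub-swarm's best (weight `theta3 .* r2`), with `r1, r2` fresh uniform(0,1)
vectors per update.  `theta1` plays the role of an inertia weight on
position and decays linearly from `w_max` to `w_min`; the schedule is
indexed by *evaluations consumed* out of the total budget `N`, so it spans
the whole run regardless of where the phase boundary falls.  Proposals that
leave the box are reflected at the violated bound; if the overshoot exceeds
the box width, the value is clamped to the violated bound, so feasibility
is guaranteed in one pass.

Personal bests update greedily on strict improvement (ties keep the
incumbent — deterministic and cheaper).  Sub-swarm and global bests are
refreshed once per iteration.  Every `regroup_interval` iterations the
particles are randomly re-partitioned; personal bests travel with the
particles, so regrouping changes only the neighborhood structure.

**Stagnation.** The swarm phase ends when the global best has improved by
at most `stagnation_tolerance` (relative, default 1%) for
`stagnation_limit` (default 4) consecutive iterations.  The window is
counted in swarm *iterations* (each costing `NP` evaluations), since the
global best can only change once per iteration; a shorter history never
triggers.  A configurable phase-1 cap (default 50% of `N`) guarantees the
refinement phase always receives budget even if stagnation never fires.

### DDS phase

The refinement phase is a greedy dynamically dimensioned search seeded with
the swarm's best solution.  At iteration `i` of a phase with `B` remaining
evaluations, each dimension enters the perturbation set independently with
probability `P_i = 1 - ln(i)/ln(B)`; an empty set is replaced by one
uniformly chosen dimension, so at least one dimension is always perturbed.
Selected dimensions receive zero-mean normal perturbations with
per-dimension standard deviation `sigma_d = R (p^U_d - p^L_d)`, `R = 0.2`;
candidates are reflected into the box and accepted only on strict
improvement.

An alternative published form of the schedule, `P_i = 1 - ln(i/B)`, is
selectable (`probability_formula: "as-printed"`).  On `1 <= i <= B` that
expression is always `>= 1`: the log of a ratio at most one is non-positive,
so after clipping to `[0, 1]` every dimension is perturbed at every
iteration and the search never narrows — contradicting both the intended
monotone decrease and the minimum-one-dimension rule.  The
`1 - ln(i)/ln(B)` form is the original DDS schedule, matches every
behavioral property expected of the phase (1 at the first iteration, 0 at
the last, monotone non-increasing), and is the default.  The alternative is
kept selectable for auditability only.

### Switching and msDOPS

DOPS switches exactly once, on stagnation or cap.  The fraction `F` of the
budget used by the swarm is not preset; it is measured at switch time, and
DDS runs the remaining `(1 - F) N` evaluations with its iteration counter
restarted at 1 against that remaining horizon.

msDOPS may switch back: each DDS phase records its entry value, and when
the incumbent has improved by at least `(1 - switchback_ratio)` times the
magnitude of the entry value (with `switchback_ratio = 0.9`, a reduction to
90% of the entry value for a positive objective), control returns to a
fresh swarm phase in which one particle is the DDS incumbent (already
evaluated, so it costs nothing) and the remaining `NP - 1` are fresh
uniform draws.  Stating the rule as a required improvement relative to
`|entry|` rather than as a fixed fraction of the entry value keeps it
well-defined for objectives that go negative (Eggholder, Styblinski–Tang),
where "90% of the entry value" would be satisfied immediately at entry.  A
switch-back also requires at least `NP` evaluations remaining; otherwise
DDS simply runs out the budget, and with an unreachable threshold msDOPS is
trace-identical to DOPS at equal seed.  Later swarm phases are capped at
half the budget remaining at their entry, so refinement always resumes.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `total_budget` (N) | 4000 | objective evaluations, the only cost unit |
| `n_particles` (NP) | 40 | swarm size |
| `n_subswarms` (k) | 5 | equal sub-swarms; NP divisible by k |
| `w_max`, `w_min` | 0.9, 0.4 | linear position-inertia schedule endpoints |
| `theta2`, `theta3` | 1.5, 1.5 | cognitive / social weights |
| `regroup_interval` (M) | 10 iterations | sub-swarm re-mixing period |
| `stagnation_tolerance` | 0.01 | relative improvement considered "no change" |
| `stagnation_limit` | 4 iterations | consecutive slow iterations before switch |
| `phase1_cap_fraction` | 0.5 | hard cap on the swarm share of the budget |
| `R` | 0.2 | DDS perturbation size, in box-width units |
| `switchback_ratio` | 0.9 | msDOPS return threshold |

The regroup interval is stated in iterations (costing `NP` evaluations
each); ten iterations mixes the sub-swarms several times within a typical
500–2000-evaluation swarm phase.  All defaults are configurable through
`DOPSConfig`, a YAML/JSON config file, or CLI flags.

## The origin-contraction property of the velocity-free update

At swarm consensus (`z = L = G = v`) the random difference terms vanish and
the update returns `theta1 * v`: a converged swarm drifts geometrically
toward the coordinate origin.  On objectives whose optimum sits elsewhere
this is a mild perturbation that the personal-best memory corrects, and the
swarm stagnates at consensus as intended.  On objectives whose optimum *is*
the origin (Ackley, Rastrigin, and most classical test functions in their
standard form), the drift plus greedy memory forms a ratchet that carries
the swarm onto the optimum with a roughly constant relative improvement per
iteration — so stagnation never triggers, the phase-1 cap ends the swarm
phase, and a swarm-*only* run continues the ratchet all the way to
floating-point zero.  Consequence: on origin-centered test functions the
swarm-only ablation is unbeatable by construction (it measures the
alignment of the update rule's fixed point with the optimum, not search
quality), and the hybrid's advantage over swarm-only is visible only on
problems whose optimum is not origin-aligned — as on the bundled
biochemical problem, where the hybrid's median final SSE beats both
swarm-only and DDS-only at equal budget.  The test suite asserts the
ablation ordering on both kinds of problem; the origin-centered 300-D
Rastrigin comparison documents this property rather than contradicting it.
The update rule is implemented exactly as specified; the behavior is a
property of the method, not of this implementation.

## Synthetic-data generator and demo problem

The bundled estimation problem is a 6-species, 8-reaction mass-action
cascade: a decaying trigger activates an enzyme `E -> Ea`; `Ea` activates a
second zymogen `Z -> Za`; `Za` feeds back positively on `E -> Ea`, induces
an inhibitor `I`, and is cleared; `I` consumes both active species.  This
reproduces the initiation / amplification / inhibition architecture of
protease networks (e.g. coagulation) at desk scale: 8 unknown rate
constants, stiff-ish nonlinear dynamics, partially observed state.  Two
training experiments differ in trigger dose (1.0 and 0.25 concentration
units); the observables are the two active species at 20 time points over
10 time units.  Nominal rate constants were chosen so that both observables
traverse rise-and-decay transients within the sampling window and every
rate constant has a nonzero finite-difference effect on the observations
(identifiability is asserted in the test suite).

Measurement noise is additive i.i.d. Gaussian with configurable standard
deviation; at the nominal parameters the expected SSE is (number of
residuals) x sd², which the tests check as a chi-square moment.  The
generator emulates *noisy, partially observed time courses at known ground
truth* — it does not emulate model misspecification, correlated or
heteroscedastic measurement error, missing samples, or inter-experiment
variability in anything but the initial condition.  Passing recovery tests
therefore demonstrate the optimizer's ability to invert a well-specified
model at realistic observability, not robustness to structural error.

The SSE objective searches multiplicative bounds `0.2 p_nom` to `5 p_nom`.
Integration failures inside the box (the stiff integrator rejecting an
absurd rate vector) are mapped to a large sentinel objective value (1e12,
far above any feasible SSE in the demo's units) and logged, so the budget
accounting and greedy acceptance proceed uninterrupted.

## Numerical choices

- ODE integration: `scipy.integrate.odeint` (LSODA), `rtol = 1e-7`,
  `atol = 1e-9`; the first requested time point is returned as the exact
  initial state.  Synthetic data and objective use the same integrator and
  tolerances, so the nominal parameters give SSE exactly 0 on noiseless
  data.
- Scaled error: a trial's best-so-far trace divided by that trial's
  *initial best* — the best objective among the `NP` random initialization
  evaluations (the single starting point for DDS-only).  Convergence curves
  are step functions aligned on the evaluation grid `1..N` by
  last-observation-carried-forward, then averaged pointwise across trials.
- Seeding: every run takes one integer seed for a `numpy` generator; batch
  trial `t` derives an independent seed below 2^31 from `(base_seed, t)`
  via `SeedSequence`, so trials are reproducible individually and in
  aggregate, and paired comparisons across variants share seeds.
- Ties in greedy acceptance (swarm personal bests and DDS) keep the
  incumbent.
- Degenerate inputs: budgets smaller than one swarm iteration raise before
  any evaluation is spent; partial swarm iterations are never performed —
  leftover sub-iteration budget in swarm-only runs is spent on fresh
  uniform samples so every variant consumes exactly `N` evaluations.

## Validation problem sizes

The shipped validation suite runs the method at its reference settings
(NP = 40, k = 5, N = 4000, T = 25 trials) on the 10-D Ackley and Rastrigin
functions; ablation orderings use 10 paired seeds; parameter recovery on
the demo cascade uses 10 trials at N = 4000 (noiseless).  The Eggholder
minimum is located by a 2049 x 2049 grid plus L-BFGS-B refinement.
Mechanical contract tests use a reduced configuration (8 particles, 2
sub-swarms, budgets of a few hundred) since they check bookkeeping, not
performance.

## Known limitations

- Stochastic or noisy objectives are unsupported; determinism of the
  objective for a fixed input is assumed by the greedy memory.
- No constraint handling beyond box bounds; no penalty-function machinery.
- The velocity-free update's origin bias (above) makes raw swarm-phase
  results on standard origin-centered test functions flattering; compare
  variants on shifted or application problems.
- Evaluation is strictly serial; there is no parallel/asynchronous
  evaluation of particles.
- The demo model is a desk-scale stand-in with synthetic data; it preserves
  the shape of kinetic-calibration problems (stiffness, partial
  observability, multiplicative bounds), not their dimensionality
  (hundreds of parameters) or data realism.
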
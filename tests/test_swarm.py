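"""Swarm phase: initialization, updates, reflection, regrouping, stagnation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dops.objective import BoundsBox, EvaluationLedger, ObjectiveSpec
from dops.swarm import (
    BudgetError,
    Particle,
    SwarmSettings,
    detect_stagnation,
    inertia_weight,
    initialize_swarm,
    reflect_bounds,
    regroup,
    swarm_iteration,
    update_particle,
)


def _sphere_spec(dim=2, half_width=10.0):
    return ObjectiveSpec(
        name="sphere",
        evaluate=lambda x: float(np.sum(x**2)),
        bounds=BoundsBox.cube(-half_width, half_width, dim),
    )


class TestSettings:
    def test_particle_count_must_divide_into_subswarms(self):
        SwarmSettings(n_particles=40, n_subswarms=5)
        with pytest.raises(ValueError):
            SwarmSettings(n_particles=40, n_subswarms=7)

    def test_weight_ordering_enforced(self):
        with pytest.raises(ValueError):
            SwarmSettings(w_max=0.4, w_min=0.9)


class TestInertiaWeight:
    def test_endpoints_match_configured_weights(self):
        assert inertia_weight(1, 4000) == pytest.approx(0.9)
        assert inertia_weight(4000, 4000) == pytest.approx(0.4)

    def test_linear_midpoint(self):
        n = 4001  # odd so the midpoint is exact
        assert inertia_weight((n + 1) // 2, n) == pytest.approx(0.65)

    def test_strictly_decreasing_over_schedule(self):
        n = 1000
        values = [inertia_weight(j, n) for j in range(1, n + 1)]
        assert np.all(np.diff(values) < 0)
        assert min(values) == pytest.approx(0.4)
        assert max(values) == pytest.approx(0.9)

    def test_degenerate_budget_rejected(self):
        with pytest.raises(ValueError):
            inertia_weight(1, 1)


class TestReflection:
    def test_interior_point_unchanged(self):
        box = BoundsBox.cube(-1.0, 1.0, 3)
        x = np.array([0.5, -0.25, 0.0])
        np.testing.assert_array_equal(reflect_bounds(x, box), x)

    def test_single_reflection(self):
        box = BoundsBox(np.array([0.0]), np.array([10.0]))
        assert reflect_bounds(np.array([12.0]), box)[0] == pytest.approx(8.0)
        assert reflect_bounds(np.array([-3.0]), box)[0] == pytest.approx(3.0)

    def test_overshoot_clamps_to_violated_bound(self):
        box = BoundsBox(np.array([0.0]), np.array([1.0]))
        assert reflect_bounds(np.array([5.0]), box)[0] == pytest.approx(1.0)
        assert reflect_bounds(np.array([-5.0]), box)[0] == pytest.approx(0.0)

    @given(
        arrays(
            float,
            4,
            elements=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_output_always_feasible(self, x):
        box = BoundsBox(np.array([-2.0, 0.0, 5.0, -1e3]), np.array([3.0, 1.0, 6.0, 1e3]))
        assert box.contains(reflect_bounds(x, box), atol=1e-9)


class _ZeroRng:
    """Stub generator forcing r1 = r2 = 0 in the particle update."""

    def uniform(self, size=None):
        return np.zeros(size)


class TestParticleUpdate:
    def test_consensus_at_origin_is_fixed_point(self, rng):
        z = np.zeros(3)
        p = Particle(position=z.copy(), personal_best=z.copy(), personal_best_value=0.0)
        out = update_particle(p, z.copy(), 0.9, SwarmSettings(), rng)
        np.testing.assert_array_equal(out, z)

    def test_forced_zero_randomness_reduces_to_inertia_term(self):
        z = np.array([1.0, -2.0])
        p = Particle(position=z.copy(), personal_best=np.ones(2), personal_best_value=1.0)
        out = update_particle(p, np.zeros(2), 0.9, SwarmSettings(), _ZeroRng())
        np.testing.assert_allclose(out, 0.9 * z)

    def test_consensus_off_origin_contracts_by_theta1(self, rng):
        # the velocity-free rule contracts a fully converged swarm toward the
        # origin: z = L = G = v gives theta1 * v regardless of randomness
        v = np.array([2.0, 4.0])
        p = Particle(position=v.copy(), personal_best=v.copy(), personal_best_value=1.0)
        out = update_particle(p, v.copy(), 0.9, SwarmSettings(), rng)
        np.testing.assert_allclose(out, 0.9 * v)

    def test_dimension_mismatch_rejected(self, rng):
        p = Particle(position=np.zeros(2), personal_best=np.zeros(2), personal_best_value=0.0)
        with pytest.raises(ValueError):
            update_particle(p, np.zeros(3), 0.9, SwarmSettings(), rng)


class TestInitialization:
    def test_equal_partition_and_evaluation_count(self, rng):
        spec = _sphere_spec(dim=4)
        settings = SwarmSettings(n_particles=40, n_subswarms=5)
        ledger = EvaluationLedger(budget=100)
        state = initialize_swarm(spec, settings, ledger, rng)
        assert ledger.consumed == 40
        assert len(state.subswarms) == 5
        assert sorted(len(s.members) for s in state.subswarms) == [8] * 5
        all_members = sorted(i for s in state.subswarms for i in s.members)
        assert all_members == list(range(40))

    def test_positions_within_bounds_and_bests_consistent(self, rng):
        spec = _sphere_spec()
        settings = SwarmSettings(n_particles=8, n_subswarms=2)
        state = initialize_swarm(spec, settings, EvaluationLedger(50), rng)
        for p in state.particles:
            assert spec.bounds.contains(p.position)
        for sub in state.subswarms:
            assert sub.swarm_best_value == min(
                state.particles[i].personal_best_value for i in sub.members
            )
        assert state.global_best_value == min(
            s.swarm_best_value for s in state.subswarms
        )

    def test_insufficient_budget_rejected(self, rng):
        spec = _sphere_spec()
        with pytest.raises(BudgetError):
            initialize_swarm(spec, SwarmSettings(), EvaluationLedger(10), rng)


class TestIteration:
    def test_costs_exactly_np_evaluations_and_improves_greedily(self, rng):
        spec = _sphere_spec(dim=1, half_width=5.0)
        settings = SwarmSettings(n_particles=8, n_subswarms=2)
        ledger = EvaluationLedger(budget=400)
        state = initialize_swarm(spec, settings, ledger, rng)
        before = state.global_best_value
        for _ in range(10):
            consumed = ledger.consumed
            swarm_iteration(state, spec, settings, ledger, rng)
            assert ledger.consumed == consumed + 8
            assert spec.bounds.contains(state.global_best)
            for p in state.particles:
                assert spec.bounds.contains(p.position)
        assert state.global_best_value <= before

    def test_beats_random_search_at_equal_budget_on_sphere(self, rng):
        spec = _sphere_spec(dim=1, half_width=5.0)
        settings = SwarmSettings(n_particles=8, n_subswarms=2)
        ledger = EvaluationLedger(budget=200)
        state = initialize_swarm(spec, settings, ledger, rng)
        while ledger.remaining >= 8:
            swarm_iteration(state, spec, settings, ledger, rng)
        # random-search oracle at the same budget and stream family
        oracle_rng = np.random.default_rng(999)
        random_best = min(
            spec.evaluate(x) for x in spec.bounds.sample(oracle_rng, 200)
        )
        assert state.global_best_value < random_best

    def test_monotone_best_history(self, rng):
        spec = _sphere_spec(dim=3)
        settings = SwarmSettings(n_particles=8, n_subswarms=2)
        ledger = EvaluationLedger(budget=400)
        state = initialize_swarm(spec, settings, ledger, rng)
        while ledger.remaining >= 8:
            swarm_iteration(state, spec, settings, ledger, rng)
        assert np.all(np.diff(state.best_history) <= 0)

    def test_partial_iteration_never_performed(self, rng):
        spec = _sphere_spec()
        settings = SwarmSettings(n_particles=8, n_subswarms=2)
        ledger = EvaluationLedger(budget=12)
        state = initialize_swarm(spec, settings, ledger, rng)
        with pytest.raises(BudgetError):
            swarm_iteration(state, spec, settings, ledger, rng)
        assert ledger.consumed == 8


class TestRegroup:
    def test_preserves_memories_and_global_best(self, rng):
        spec = _sphere_spec(dim=3)
        settings = SwarmSettings(n_particles=12, n_subswarms=3)
        state = initialize_swarm(spec, settings, EvaluationLedger(50), rng)
        before_best = state.global_best_value
        before_values = sorted(p.personal_best_value for p in state.particles)
        regroup(state, rng)
        assert sorted(p.personal_best_value for p in state.particles) == before_values
        assert state.global_best_value == before_best
        assert sorted(len(s.members) for s in state.subswarms) == [4, 4, 4]

    def test_reproducible_partition_under_fixed_seed(self):
        spec = _sphere_spec(dim=3)
        settings = SwarmSettings(n_particles=12, n_subswarms=3)
        memberships = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            state = initialize_swarm(spec, settings, EvaluationLedger(50), rng)
            regroup(state, rng)
            memberships.append([tuple(s.members) for s in state.subswarms])
        assert memberships[0] == memberships[1]


class TestStagnation:
    def test_slow_improvement_window_triggers(self):
        assert detect_stagnation([100, 99.9, 99.85, 99.84, 99.84], 0.01, 4)

    def test_fast_improvement_does_not_trigger(self):
        assert not detect_stagnation([100, 50, 25, 12, 6], 0.01, 4)

    def test_insufficient_history_is_not_stagnation(self):
        assert not detect_stagnation([10, 10, 10], 0.01, 4)

    def test_single_fast_step_inside_window_resets(self):
        assert not detect_stagnation([100, 99.9, 50, 49.9, 49.85], 0.01, 4)
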
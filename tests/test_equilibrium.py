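import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divallele import (
    ao_threshold,
    build_ao_f,
    build_symmetric_f,
    iterate_to_convergence,
    make_state,
    marginal_fitness,
    population_fitness,
    solve_equilibrium,
    step_dynamics,
)
from divallele.equilibrium import result_to_json

from .conftest import random_stable_system

seeds = st.integers(0, 2**31 - 1)


class TestSolve:
    def test_three_allele_worked_example(self, stable_daa_matrix):
        """The stable layout keeps all three alleles at 15/23, 7/23, 1/23."""
        res = solve_equilibrium(stable_daa_matrix)
        assert res.status == "stable"
        assert np.array_equal(res.surviving, [0, 1, 2])
        assert np.allclose(res.proportions, [15 / 23, 7 / 23, 1 / 23], atol=1e-10)
        assert res.eliminations == ()

    def test_collapsing_example_single_survivor(self, unstable_daa_matrix):
        res = solve_equilibrium(unstable_daa_matrix)
        assert res.status == "stable"
        assert np.array_equal(res.surviving, [0])
        assert res.proportions[0] == pytest.approx(1.0)
        assert res.population_fitness == pytest.approx(0.8)
        # both weaker alleles drop in the first elimination round
        assert [sorted(e.tolist()) for e in res.eliminations] == [[1, 2]]

    @pytest.mark.parametrize("k", [2, 3, 6])
    def test_equal_merit_symmetric_od_is_uniform(self, k):
        res = solve_equilibrium(build_symmetric_f(np.full(k, 0.4)))
        assert np.allclose(res.proportions, 1.0 / k, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(seeds)
    def test_two_allele_closed_form(self, seed):
        """p1 = (f12 - w2) / (2 f12 - w1 - w2) for an overdominant pair."""
        rng = np.random.default_rng(seed)
        w1, w2 = rng.uniform(0.05, 0.95, 2)
        f12 = rng.uniform(max(w1, w2) + 0.01, 1.0)
        F = np.array([[w1, f12], [f12, w2]])
        res = solve_equilibrium(F)
        expected = (f12 - w2) / (2 * f12 - w1 - w2)
        assert np.allclose(res.proportions, [expected, 1 - expected], atol=1e-10)
        # brute-force time stepping agrees
        dyn = iterate_to_convergence(F, tol=1e-12)
        assert np.allclose(dyn.proportions, res.proportions, atol=1e-8)

    def test_exactly_singular_flagged(self):
        res = solve_equilibrium(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert res.status == "singular"

    def test_near_singular_flagged(self):
        eps = 1e-12
        res = solve_equilibrium(np.array([[0.5, 0.5 + eps], [0.5 + eps, 0.5]]))
        assert res.status == "singular"

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            solve_equilibrium(np.array([[0.5, 0.9], [0.2, 0.5]]))

    def test_single_allele(self):
        res = solve_equilibrium(np.array([[0.7]]))
        assert res.proportions[0] == 1.0
        assert res.population_fitness == pytest.approx(0.7)

    def test_one_at_a_time_option_same_result(self, unstable_daa_matrix):
        res = solve_equilibrium(unstable_daa_matrix, one_at_a_time=True)
        assert np.array_equal(res.surviving, [0])

    def test_json_serialization(self, stable_daa_matrix):
        import json

        res = solve_equilibrium(stable_daa_matrix)
        payload = json.loads(result_to_json(res))
        assert payload["survivors"] == ["A1", "A2", "A3"]
        assert payload["status"] == "stable"
        assert payload["proportions"][0] == pytest.approx(15 / 23)


class TestDynamics:
    def test_equilibrium_is_fixed_point(self, stable_daa_matrix):
        res = solve_equilibrium(stable_daa_matrix)
        state = make_state(stable_daa_matrix, res.full_proportions())
        nxt = step_dynamics(stable_daa_matrix, state)
        assert np.allclose(nxt.proportions, state.proportions, atol=1e-12)

    def test_vertex_is_fixed_point(self, stable_daa_matrix):
        state = make_state(stable_daa_matrix, [1.0, 0.0, 0.0])
        nxt = step_dynamics(stable_daa_matrix, state)
        assert np.allclose(nxt.proportions, [1.0, 0.0, 0.0])

    def test_single_allele_stays(self):
        state = make_state(np.array([[0.5]]), [1.0])
        assert step_dynamics(np.array([[0.5]]), state).proportions[0] == 1.0

    def test_zero_fitness_population_rejected(self):
        F = np.zeros((2, 2))
        state = make_state(F, [0.5, 0.5])
        with pytest.raises(ZeroDivisionError):
            step_dynamics(F, state)

    @settings(max_examples=60, deadline=None)
    @given(seeds, st.integers(2, 8))
    def test_simplex_conservation_and_monotone_fitness(self, seed, k):
        """Proportions stay on the simplex and population fitness never
        decreases along trajectories (symmetric viability selection)."""
        rng = np.random.default_rng(seed)
        F = random_stable_system(rng, k)
        p = rng.dirichlet(np.ones(k))
        state = make_state(F, p)
        for _ in range(25):
            nxt = step_dynamics(F, state)
            assert abs(nxt.proportions.sum() - 1.0) < 1e-12
            assert nxt.population_fitness >= state.population_fitness - 1e-12
            state = nxt

    def test_collapsing_example_decays_to_best(self, unstable_daa_matrix):
        """A2 and A3 are only weakly selected against near the A1 vertex, so
        their proportions decay algebraically; a loose prune threshold still
        identifies the sole survivor."""
        res = iterate_to_convergence(unstable_daa_matrix, tol=1e-9, prune=1e-4)
        assert np.array_equal(res.surviving, [0])
        assert res.proportions[0] == pytest.approx(1.0)


class TestOracleAgreement:
    @settings(max_examples=25, deadline=None)
    @given(seeds, st.integers(2, 8))
    def test_solver_matches_time_stepping(self, seed, k):
        """Linear solve with elimination and discrete-time iteration find the
        same survivors and proportions. Alleles that are only weakly selected
        against decay algebraically, so when the iteration has not yet pruned
        them the comparison falls back to closeness of the full proportion
        vectors."""
        rng = np.random.default_rng(seed)
        F = random_stable_system(rng, k)
        res = solve_equilibrium(F)
        if res.status != "stable":
            return
        dyn = iterate_to_convergence(F, tol=1e-12, prune=1e-6, max_steps=400_000)
        if np.array_equal(res.surviving, dyn.surviving):
            assert np.allclose(res.proportions, dyn.proportions, atol=1e-8)
        else:
            # distinct boundary equilibria (or not-yet-pruned weakly selected
            # alleles): the dynamics must reach a state at least as fit as
            # the procedure's answer
            assert dyn.population_fitness >= res.population_fitness - 1e-4

    @settings(max_examples=40, deadline=None)
    @given(seeds, st.integers(2, 8))
    def test_equal_marginals_at_equilibrium(self, seed, k):
        rng = np.random.default_rng(seed)
        F = random_stable_system(rng, k)
        res = solve_equilibrium(F)
        if res.status != "stable":
            return
        sub = F.submatrix(res.surviving)
        wm = sub @ res.proportions
        assert np.max(np.abs(wm - res.population_fitness)) < 1e-9

    @settings(max_examples=40, deadline=None)
    @given(seeds, st.integers(2, 8))
    def test_ao_persistence_iff_above_threshold(self, seed, k):
        """All k alleles persist under AO exactly when every merit exceeds
        ((k-1)/k) x harmonic mean."""
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 0.95, k)
        res = solve_equilibrium(build_ao_f(w))
        report = ao_threshold(w)
        if res.status != "stable":
            return
        assert (res.surviving.size == k) == report.stable

    @settings(max_examples=30, deadline=None)
    @given(seeds, st.integers(2, 8))
    def test_symmetric_od_retains_all_alleles(self, seed, k):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 0.95, k)
        res = solve_equilibrium(build_symmetric_f(w))
        assert res.surviving.size == k


class TestFitnessForms:
    def test_all_ones_matrix(self):
        p = np.array([0.2, 0.3, 0.5])
        assert population_fitness(np.ones((3, 3)), p) == pytest.approx(1.0)

    def test_diagonal_matrix(self):
        w = 0.6
        F = np.eye(3) * w
        p = np.full(3, 1 / 3)
        assert np.allclose(marginal_fitness(F, p), w * p)
        assert population_fitness(F, p) == pytest.approx(w * np.sum(p**2))

    def test_marginals_equal_at_worked_equilibrium(self, stable_daa_matrix):
        res = solve_equilibrium(stable_daa_matrix)
        wm = marginal_fitness(stable_daa_matrix, res.full_proportions())
        assert np.allclose(wm, res.population_fitness, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            marginal_fitness(np.eye(3) * 0.5, np.array([0.5, 0.5]))
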
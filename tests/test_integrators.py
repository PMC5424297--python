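import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from massaction import (
    NewtonConvergenceError,
    ReactionModel,
    SingularMatrixError,
    UnsupportedOrderError,
    bdf_coefficients,
    bdf_step,
    build_encoding,
    error_and_delta,
    evaluate_jacobian,
    lu_solve,
    newton_raphson,
    rkf_step,
    step_control,
)
from massaction.integrators import DELTA_MAX, LUFactorization


def _decay_system(k: float = 1.0):
    """A -> B with rate k; component A obeys dX/dt = -k X."""
    model = ReactionModel(
        reactant_matrix=[[1, 0]],
        product_matrix=[[0, 1]],
        kinetic_constants=[k],
        initial_state=[1.0, 0.0],
        sampling_times=[0.0, 1.0],
    )
    return build_encoding(model)


def _equilibrium_system():
    """A <-> B with k = (1, 2) at the fixed point X = (2, 1)."""
    model = ReactionModel(
        reactant_matrix=[[1, 0], [0, 1]],
        product_matrix=[[0, 1], [1, 0]],
        kinetic_constants=[1.0, 2.0],
        initial_state=[2.0, 1.0],
        sampling_times=[0.0, 1.0],
    )
    return build_encoding(model)


def _nonlinear_system():
    """A + B <-> C: a smooth nonlinear test model."""
    model = ReactionModel(
        reactant_matrix=[[1, 1, 0], [0, 0, 1]],
        product_matrix=[[0, 0, 1], [1, 1, 0]],
        kinetic_constants=[1.0, 0.5],
        initial_state=[1.0, 0.8, 0.3],
        sampling_times=[0.0, 1.0],
    )
    return build_encoding(model)


class TestErrorAndDelta:
    def test_delta_is_the_safety_factor_when_error_meets_tolerance(self):
        # |w - u| = dt * eps so ER = eps exactly -> delta = 0.84
        # (dt a power of two keeps the product/quotient exact)
        dt, eps = 0.25, np.array([1e-6, 1e-8])
        u = np.zeros(2)
        w = dt * eps
        er, delta = error_and_delta(u, w, dt, eps)
        np.testing.assert_array_equal(er, eps)
        np.testing.assert_array_equal(delta, [0.84, 0.84])

    def test_zero_error_is_capped_at_delta_max(self):
        u = np.array([1.0])
        er, delta = error_and_delta(u, u.copy(), 0.1, np.array([1e-12]))
        assert er[0] == 0.0
        assert delta[0] == DELTA_MAX

    def test_sixteenfold_slack_doubles_the_step(self):
        dt = 0.5
        u = np.array([0.0])
        w = np.array([dt * 1.0])  # ER = 1
        er, delta = error_and_delta(u, w, dt, np.array([16.0]))
        assert er[0] == pytest.approx(1.0)
        assert delta[0] == pytest.approx(0.84 * 2.0)

    def test_invalid_inputs_are_rejected(self):
        u = np.array([1.0])
        with pytest.raises(ValueError, match="dt"):
            error_and_delta(u, u, 0.0, np.array([1e-6]))
        with pytest.raises(ValueError, match="tolerance"):
            error_and_delta(u, u, 0.1, np.array([0.0]))

    @settings(derandomize=True, max_examples=50)
    @given(
        gap=st.floats(1e-12, 1e3),
        dt=st.floats(1e-6, 10.0),
        eps=st.floats(1e-14, 1.0),
    )
    def test_controller_invariants_hold_for_arbitrary_inputs(
        self, gap, dt, eps
    ):
        u = np.array([0.3])
        w = u + gap
        er, delta = error_and_delta(u, w, dt, np.array([eps]))
        assert er[0] == pytest.approx(abs(w[0] - u[0]) / dt)
        assert 0.0 < delta[0] <= DELTA_MAX
        # monotone: more slack never shrinks the step multiplier
        _, delta2 = error_and_delta(u, w, dt, np.array([2 * eps]))
        assert delta2[0] >= delta[0]


class TestRKFStep:
    def test_exactly_six_derivative_stages(self):
        system = _decay_system()
        result = rkf_step(
            system, np.array([1.0, 0.0]), 0.0, 0.1, np.full(2, 1e-12)
        )
        assert len(result.stages) == 6
        assert all(s.shape == (2,) for s in result.stages)

    def test_fifth_order_estimate_tracks_the_exponential_solution(self):
        system = _decay_system(k=1.0)
        result = rkf_step(
            system, np.array([1.0, 0.0]), 0.0, 0.1, np.full(2, 1e-12)
        )
        assert result.u[0] == pytest.approx(math.exp(-0.1), abs=1e-7)

    def test_equilibrium_is_a_fixed_point_with_zero_error(self):
        system = _equilibrium_system()
        X = np.array([2.0, 1.0])
        result = rkf_step(system, X, 0.0, 0.1, np.full(2, 1e-12))
        np.testing.assert_array_equal(result.u, X)
        np.testing.assert_array_equal(result.w, X)
        assert np.all(result.er == 0.0)
        assert np.all(result.delta == DELTA_MAX)

    def test_error_measure_scales_as_dt_to_the_fourth(self):
        system = _nonlinear_system()
        X = np.array([1.0, 0.8, 0.3])
        eps = np.full(3, 1e-12)
        er_h = rkf_step(system, X, 0.0, 0.05, eps).er.max()
        er_h2 = rkf_step(system, X, 0.0, 0.025, eps).er.max()
        assert 8.0 < er_h / er_h2 < 32.0

    def test_nonpositive_step_is_rejected(self):
        system = _decay_system()
        with pytest.raises(ValueError, match="dt"):
            rkf_step(system, np.array([1.0, 0.0]), 0.0, 0.0, np.full(2, 1e-12))


class TestStepControl:
    def _result(self, er, delta):
        x = np.zeros(len(er))
        from massaction import RKFStepResult

        return RKFStepResult(
            stages=tuple(np.zeros(len(er)) for _ in range(6)),
            u=np.arange(float(len(er))),
            w=x,
            er=np.asarray(er, dtype=float),
            delta=np.asarray(delta, dtype=float),
        )

    def test_within_tolerance_accepts_u_and_grows_dt(self):
        result = self._result([1e-13, 1e-14], [2.0, 3.0])
        decision = step_control(result, np.full(2, 1e-12), 0.1, 1e-6)
        assert decision.action == "accept"
        np.testing.assert_array_equal(decision.new_state, result.u)
        assert decision.new_dt == pytest.approx(0.1 * 2.0)

    def test_rejection_with_acceptable_step_retries_at_min_delta(self):
        result = self._result([1e-3], [1e-3])
        decision = step_control(result, np.array([1e-12]), 0.1, 1e-6)
        assert decision.action == "retry"
        assert decision.new_dt == pytest.approx(1e-4)

    def test_rejection_below_the_threshold_switches_to_bdf(self):
        result = self._result([1e-3], [1e-7])
        decision = step_control(result, np.array([1e-12]), 0.1, 1e-6)
        assert decision.action == "switch_to_bdf"
        assert decision.new_dt < 1e-6


class TestBDFCoefficients:
    def test_first_order_is_backward_euler(self):
        c = bdf_coefficients(1)
        np.testing.assert_array_equal(c.alphas, [1.0, -1.0])
        assert c.beta0 == 1.0

    def test_second_order_values(self):
        c = bdf_coefficients(2)
        assert c.alphas_exact == (
            Fraction(1),
            Fraction(-4, 3),
            Fraction(1, 3),
        )
        assert c.beta0_exact == Fraction(2, 3)

    @pytest.mark.parametrize("q", range(1, 7))
    def test_order_condition_identities_hold_exactly(self, q):
        c = bdf_coefficients(q)
        assert c.alphas_exact[0] == 1
        assert sum(c.alphas_exact) == 0  # exact on constants
        assert c.beta0_exact == -sum(
            i * a for i, a in enumerate(c.alphas_exact)
        )  # exact on linear functions
        assert c.beta0 > 0

    @pytest.mark.parametrize("q", [0, 7, -1, 2.5])
    def test_orders_outside_one_to_six_are_refused(self, q):
        with pytest.raises(UnsupportedOrderError):
            bdf_coefficients(q)


class TestLU:
    def test_identity_returns_the_rhs(self):
        rhs = np.array([3.0, -1.0, 2.0])
        np.testing.assert_array_equal(lu_solve(np.eye(3), rhs), rhs)

    def test_diagonal_system(self):
        x = lu_solve(np.array([[2.0, 0.0], [0.0, 4.0]]), np.array([2.0, 8.0]))
        np.testing.assert_allclose(x, [1.0, 2.0])

    def test_singular_matrix_is_detected(self):
        with pytest.raises(SingularMatrixError):
            lu_solve(np.array([[1.0, 2.0], [2.0, 4.0]]), np.array([1.0, 1.0]))

    def test_factorization_is_reusable_across_right_hand_sides(self):
        rng = np.random.default_rng(5)
        A = rng.random((4, 4)) + 4 * np.eye(4)
        fact = LUFactorization(A)
        for _ in range(3):
            b = rng.random(4)
            np.testing.assert_allclose(A @ fact.solve(b), b, atol=1e-12)


class TestNewtonRaphson:
    def test_converges_to_the_root_of_a_scalar_quadratic(self):
        root = newton_raphson(
            lambda z: z * z - 4.0,
            lambda z: np.atleast_2d(2.0 * z),
            np.array([3.0]),
            eps_nr=1e-6,
        )
        assert root[0] == pytest.approx(2.0, abs=1e-6)

    def test_exact_root_returns_after_one_zero_update(self):
        calls = {"n": 0}

        def residual(z):
            calls["n"] += 1
            return z * z - 4.0

        root = newton_raphson(
            residual, lambda z: np.atleast_2d(2.0 * z), np.array([2.0])
        )
        assert root[0] == 2.0
        assert calls["n"] == 1

    def test_iteration_cap_is_enforced(self):
        with pytest.raises(NewtonConvergenceError):
            newton_raphson(
                lambda z: z * z - 4.0,
                lambda z: np.atleast_2d(2.0 * z),
                np.array([30.0]),
                eps_nr=1e-12,
                max_it=1,
            )

    def test_singular_iteration_matrix_is_reported(self):
        with pytest.raises(SingularMatrixError):
            newton_raphson(
                lambda z: z,
                lambda z: np.zeros((1, 1)),
                np.array([1.0]),
            )


class TestBDFStep:
    def test_backward_euler_on_linear_decay_is_the_closed_form(self):
        system = _decay_system(k=1.0)
        X = bdf_step(system, [np.array([1.0, 0.0])], dt=0.1, q=1)
        assert X[0] == pytest.approx(1.0 / 1.1, rel=1e-14)

    def test_equilibrium_history_is_a_fixed_point(self):
        system = _equilibrium_system()
        X_star = np.array([2.0, 1.0])
        X = bdf_step(system, [X_star, X_star], dt=0.1, q=2)
        np.testing.assert_allclose(X, X_star, rtol=1e-12)

    def test_bdf2_matches_the_scalar_recurrence(self):
        k, dt = 1.0, 0.1
        system = _decay_system(k=k)
        # two backward-Euler-spaced history states
        x1 = 1.0 / (1.0 + k * dt)
        hist = [np.array([1.0, 0.0]), np.array([x1, 1.0 - x1])]
        X = bdf_step(system, hist, dt=dt, q=2)
        want = (4.0 / 3.0 * x1 - 1.0 / 3.0 * 1.0) / (1.0 + 2.0 / 3.0 * k * dt)
        assert X[0] == pytest.approx(want, rel=1e-12)

    def test_order_one_equals_the_direct_linear_solve(self):
        # for a linear (purely unimolecular) system, backward Euler is
        # (I - dt J)^{-1} X_n up to LU round-off
        model = ReactionModel(
            reactant_matrix=[[1, 0, 0], [0, 1, 0], [0, 0, 1]],
            product_matrix=[[0, 1, 0], [0, 0, 1], [1, 0, 0]],
            kinetic_constants=[1.0, 2.0, 0.5],
            initial_state=[1.0, 0.5, 0.2],
            sampling_times=[0.0, 1.0],
        )
        system = build_encoding(model)
        X_n = np.array([1.0, 0.5, 0.2])
        dt = 0.2
        J = evaluate_jacobian(system, X_n)
        direct = np.linalg.solve(np.eye(3) - dt * J, X_n)
        stepped = bdf_step(system, [X_n], dt=dt, q=1, eps_nr=1e-14)
        np.testing.assert_allclose(stepped, direct, rtol=1e-12)

    def test_missing_history_is_rejected(self):
        system = _decay_system()
        with pytest.raises(ValueError, match="history"):
            bdf_step(system, [np.array([1.0, 0.0])], dt=0.1, q=2)

    def test_global_error_of_backward_euler_is_first_order(self):
        # dX/dt = -X over [0, 1]: halving dt halves the global error
        system = _decay_system(k=1.0)

        def run(dt):
            X = np.array([1.0, 0.0])
            for _ in range(round(1.0 / dt)):
                X = bdf_step(system, [X], dt=dt, q=1, eps_nr=1e-13)
            return abs(X[0] - math.exp(-1.0))

        ratio = run(0.02) / run(0.01)
        assert 1.7 < ratio < 2.3
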
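"""Numerical integration kernels: explicit RKF45 and implicit BDF.

The explicit path is the classical Fehlberg embedded 4(5) pair: six
derivative stages l1..l6 yield two approximations of X(t+dt) — the
fifth-order estimate ``u`` (accepted as the new state, i.e. local
extrapolation) and the fourth-order companion ``w``.  Their difference
drives the per-species error measure and step multiplier

    ER = |w - u| / dt,        delta = 0.84 (eps / ER)^(1/4),

with ``delta`` capped at ``delta_max`` (the cap also absorbs ER = 0).
A step is accepted iff ``ER_j <= eps_j`` for every species; otherwise
it is retried at ``dt * min_j delta_j``, and when that step-size falls
below the switching threshold ``eps_s`` the system is declared stiff
and control passes to the implicit path.

The implicit path is the backward differentiation formula of order
q in 1..6 (orders above 6 are unstable and refused),

    sum_{i=0}^{q} alpha_i X(t - i dt) = dt beta_0 f(t, X(t)),

with ``alpha_0 = 1`` and coefficients determined exactly (they satisfy
``sum_i alpha_i = 0`` and ``beta_0 = -sum_i i alpha_i``).  The
nonlinear system of each implicit step is solved by a *modified*
Newton-Raphson iteration: the iteration matrix ``I - dt beta_0 J`` is
LU-factorized once at the initial guess and the factors are reused,
with a single re-factorization if the updates stagnate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .ode_encoding import (
    CompressedODESystem,
    evaluate_derivatives,
    evaluate_jacobian,
)

__all__ = [
    "RKFStepResult",
    "StepDecision",
    "BDFCoefficients",
    "StepFailureError",
    "UnsupportedOrderError",
    "NewtonConvergenceError",
    "SingularMatrixError",
    "LUFactorization",
    "rkf_step",
    "error_and_delta",
    "step_control",
    "bdf_coefficients",
    "bdf_step",
    "newton_raphson",
    "lu_solve",
    "DELTA_MAX",
]

#: default cap on the step multiplier (also used when ER = 0)
DELTA_MAX = 4.0


class StepFailureError(ArithmeticError):
    """An explicit stage produced a non-finite value."""


class UnsupportedOrderError(ValueError):
    """BDF order outside 1..6."""


class NewtonConvergenceError(ArithmeticError):
    """Newton-Raphson failed to converge within the iteration cap."""


class SingularMatrixError(np.linalg.LinAlgError):
    """The (iteration) matrix is singular to working precision."""


# ---------------------------------------------------------------------------
# explicit path: Fehlberg 4(5)

_RKF_A = (
    (),
    (1 / 4,),
    (3 / 32, 9 / 32),
    (1932 / 2197, -7200 / 2197, 7296 / 2197),
    (439 / 216, -8.0, 3680 / 513, -845 / 4104),
    (-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40),
)
_RKF_C = (0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2)
_RKF_B5 = (16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55)
_RKF_B4 = (25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0)


@dataclass
class RKFStepResult:
    """One explicit trial step: stages, embedded pair and controller data."""

    stages: tuple[np.ndarray, ...]  #: the six derivative stages l1..l6
    u: np.ndarray  #: fifth-order candidate state at t + dt
    w: np.ndarray  #: fourth-order companion estimate
    er: np.ndarray  #: per-species error measure |w - u| / dt
    delta: np.ndarray  #: per-species step multiplier


def error_and_delta(
    u: np.ndarray,
    w: np.ndarray,
    dt: float,
    eps: np.ndarray,
    delta_max: float = DELTA_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species error measure and step multiplier of the controller.

    ``ER = |w - u| / dt`` componentwise and
    ``delta = 0.84 (eps / ER)^(1/4)``, clamped to ``delta_max`` (which
    also covers the ER = 0 division).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("all tolerances must be positive")
    er = np.abs(w - u) / dt
    with np.errstate(divide="ignore", over="ignore"):
        delta = 0.84 * (eps / er) ** 0.25
    delta = np.where(er == 0.0, delta_max, np.minimum(delta, delta_max))
    return er, delta


def rkf_step(
    system: CompressedODESystem,
    X: np.ndarray,
    t: float,
    dt: float,
    eps: np.ndarray,
    delta_max: float = DELTA_MAX,
) -> RKFStepResult:
    """One trial Runge-Kutta-Fehlberg 4(5) step of size ``dt`` from ``X``.

    Evaluates exactly six derivative stages; raises
    :class:`StepFailureError` if any stage or candidate state is
    non-finite (e.g. overflow on a wildly unstable step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    X = np.asarray(X, dtype=float)
    stages: list[np.ndarray] = []
    for i in range(6):
        Y = X
        if i:
            acc = _RKF_A[i][0] * stages[0]
            for a, l in zip(_RKF_A[i][1:], stages[1:]):
                if a:
                    acc = acc + a * l
            Y = X + dt * acc
        li = evaluate_derivatives(system, Y)
        if not np.all(np.isfinite(li)):
            raise StepFailureError(f"non-finite stage l{i + 1} at dt = {dt!r}")
        stages.append(li)
    u = X + dt * sum(b * l for b, l in zip(_RKF_B5, stages) if b)
    w = X + dt * sum(b * l for b, l in zip(_RKF_B4, stages) if b)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(w))):
        raise StepFailureError(f"non-finite candidate state at dt = {dt!r}")
    er, delta = error_and_delta(u, w, dt, eps, delta_max)
    return RKFStepResult(stages=tuple(stages), u=u, w=w, er=er, delta=delta)


@dataclass
class StepDecision:
    """Outcome of the acceptance test on a trial explicit step."""

    action: str  #: "accept" | "retry" | "switch_to_bdf"
    new_state: np.ndarray | None = None  #: accepted state (accept only)
    new_dt: float | None = None  #: controller-updated step-size


def step_control(
    result: RKFStepResult,
    eps: np.ndarray,
    dt: float,
    eps_s: float,
) -> StepDecision:
    """Accept, retry or declare stiffness for a trial explicit step.

    The step is accepted iff ``ER_j <= eps_j`` for all species, with
    ``u`` as the new state.  On rejection the step-size becomes
    ``dt * min_j delta_j``; if that is still >= ``eps_s`` the step is
    retried, otherwise the system is considered stiff and the decision
    is to switch to the implicit BDF path.
    """
    eps = np.asarray(eps, dtype=float)
    new_dt = float(dt * result.delta.min())
    if np.all(result.er <= eps):
        return StepDecision("accept", new_state=result.u, new_dt=new_dt)
    if new_dt >= eps_s:
        return StepDecision("retry", new_dt=new_dt)
    return StepDecision("switch_to_bdf", new_dt=new_dt)


# ---------------------------------------------------------------------------
# implicit path: BDF orders 1..6

_BDF_TABLE: dict[int, tuple[tuple[Fraction, ...], Fraction]] = {
    1: ((Fraction(1), Fraction(-1)), Fraction(1)),
    2: ((Fraction(1), Fraction(-4, 3), Fraction(1, 3)), Fraction(2, 3)),
    3: (
        (Fraction(1), Fraction(-18, 11), Fraction(9, 11), Fraction(-2, 11)),
        Fraction(6, 11),
    ),
    4: (
        (
            Fraction(1),
            Fraction(-48, 25),
            Fraction(36, 25),
            Fraction(-16, 25),
            Fraction(3, 25),
        ),
        Fraction(12, 25),
    ),
    5: (
        (
            Fraction(1),
            Fraction(-300, 137),
            Fraction(300, 137),
            Fraction(-200, 137),
            Fraction(75, 137),
            Fraction(-12, 137),
        ),
        Fraction(60, 137),
    ),
    6: (
        (
            Fraction(1),
            Fraction(-360, 147),
            Fraction(450, 147),
            Fraction(-400, 147),
            Fraction(225, 147),
            Fraction(-72, 147),
            Fraction(10, 147),
        ),
        Fraction(60, 147),
    ),
}


@dataclass(frozen=True)
class BDFCoefficients:
    """Coefficients alpha_0..alpha_q (alpha_0 = 1) and beta_0 of order q.

    Exact rational values are kept alongside the float arrays so that
    the defining identities ``sum_i alpha_i = 0`` (exactness on
    constants) and ``beta_0 = -sum_i i alpha_i`` (exactness on linear
    functions) can be checked without round-off.
    """

    order: int
    alphas: np.ndarray
    beta0: float
    alphas_exact: tuple[Fraction, ...]
    beta0_exact: Fraction


def bdf_coefficients(q: int) -> BDFCoefficients:
    """Coefficient set of the order-q BDF; q outside 1..6 is refused."""
    if not isinstance(q, (int, np.integer)) or isinstance(q, bool):
        raise UnsupportedOrderError(f"BDF order must be an integer, got {q!r}")
    if not 1 <= q <= 6:
        raise UnsupportedOrderError(
            f"BDF of order {q} is not supported: orders above 6 are "
            "numerically unstable, orders below 1 are meaningless"
        )
    alphas_exact, beta0_exact = _BDF_TABLE[int(q)]
    return BDFCoefficients(
        order=int(q),
        alphas=np.array([float(a) for a in alphas_exact]),
        beta0=float(beta0_exact),
        alphas_exact=alphas_exact,
        beta0_exact=beta0_exact,
    )


class LUFactorization:
    """LU factorization with partial pivoting, reusable across solves."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError(f"matrix must be square, got shape {matrix.shape}")
        if not np.all(np.isfinite(matrix)):
            raise SingularMatrixError("matrix contains non-finite entries")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            self._lu, self._piv = scipy.linalg.lu_factor(
                matrix, check_finite=False
            )
        diag = np.abs(np.diag(self._lu))
        if np.any(diag == 0.0) or not np.all(np.isfinite(diag)):
            raise SingularMatrixError("matrix is singular to working precision")
        self.shape = matrix.shape

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = np.asarray(rhs, dtype=float)
        if rhs.shape[0] != self.shape[0]:
            raise ValueError("right-hand side length mismatch")
        return scipy.linalg.lu_solve((self._lu, self._piv), rhs,
                                     check_finite=False)


def lu_solve(matrix: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``matrix @ x = rhs`` via LU with partial pivoting."""
    return LUFactorization(matrix).solve(rhs)


def newton_raphson(
    residual_evaluator: Callable[[np.ndarray], np.ndarray],
    jacobian_evaluator: Callable[[np.ndarray], np.ndarray],
    z0: np.ndarray,
    eps_nr: float = 1e-6,
    max_it: int = 10_000,
) -> np.ndarray:
    """Modified Newton-Raphson with a frozen LU-factorized iteration matrix.

    Iterates ``z <- z - solve(J(z0), G(z))`` with the factorization
    computed once at ``z0`` and reused; convergence is declared when the
    max-norm of the update drops below ``eps_nr``.  If the update norms
    stagnate (successive ratio > 0.9 three times in a row) the matrix
    is re-evaluated and re-factorized once at the current iterate before
    the iteration is allowed to fail with
    :class:`NewtonConvergenceError`.
    """
    if max_it < 1:
        raise ValueError("max_it must be >= 1")
    z = np.atleast_1d(np.asarray(z0, dtype=float)).copy()
    lu = LUFactorization(np.atleast_2d(jacobian_evaluator(z)))
    refactored = False
    stagnant = 0
    prev_norm = np.inf
    for _ in range(max_it):
        g = np.atleast_1d(np.asarray(residual_evaluator(z), dtype=float))
        step = lu.solve(g)
        z = z - step
        norm = float(np.max(np.abs(step))) if step.size else 0.0
        if not np.isfinite(norm):
            raise NewtonConvergenceError("non-finite Newton update")
        if norm < eps_nr:
            return z
        stagnant = stagnant + 1 if norm > 0.9 * prev_norm else 0
        if stagnant >= 3 and not refactored:
            lu = LUFactorization(np.atleast_2d(jacobian_evaluator(z)))
            refactored = True
            stagnant = 0
        prev_norm = norm
    raise NewtonConvergenceError(
        f"no convergence within {max_it} iterations (last update {prev_norm:g})"
    )


def bdf_step(
    system: CompressedODESystem,
    history: Sequence[np.ndarray],
    dt: float,
    q: int,
    eps_nr: float = 1e-6,
    max_it: int = 10_000,
) -> np.ndarray:
    """One implicit BDF step of order ``q`` and size ``dt``.

    ``history`` holds at least ``q`` previous states at uniform spacing
    ``dt``, most recent *last*.  The step solves

        G(z) = z + sum_{i=1..q} alpha_i X_{t-(i-1)dt} - dt beta_0 f(z) = 0

    by the modified Newton iteration with iteration matrix
    ``I - dt beta_0 J(z)``, starting from the most recent state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    coeffs = bdf_coefficients(q)
    hist = [np.asarray(h, dtype=float) for h in history]
    if len(hist) < coeffs.order:
        raise ValueError(
            f"BDF of order {coeffs.order} needs {coeffs.order} history "
            f"states, got {len(hist)}"
        )
    n = system.n_species
    const = np.zeros(n)
    for i in range(1, coeffs.order + 1):
        const += coeffs.alphas[i] * hist[-i]
    scale = dt * coeffs.beta0
    identity = np.eye(n)

    def residual(z: np.ndarray) -> np.ndarray:
        return z + const - scale * evaluate_derivatives(system, z)

    def iteration_matrix(z: np.ndarray) -> np.ndarray:
        return identity - scale * evaluate_jacobian(system, z)

    return newton_raphson(residual, iteration_matrix, hist[-1], eps_nr, max_it)
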
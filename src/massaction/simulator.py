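"""Simulation driver: sampling, adaptive stepping and stiffness switching.

The run is organised in six phases.  The compressed ODE encoding is
built once up front (P1).  The state is recorded whenever the current
time coincides with a sampling instant (P2).  Between instants the
driver takes explicit RKF45 trial steps (P3) and applies the
acceptance rule (P4): accepted steps advance the state, rejected ones
shrink the step-size by ``min_j delta_j``, and when the shrunken
step-size falls below ``eps_s`` the system is declared stiff and one
or more implicit BDF macro-steps of length ``dt_bdf`` are taken (P5),
after which explicit stepping resumes at the initial step-size
``dt0``.  The run terminates exactly at the last sampling instant
(P6).

The step-size is clamped so integration lands exactly on every
sampling instant; no interpolation is performed.  The step-size also
grows on accepted steps, ``dt <- min(dt * min_j delta_j, dt_max)``
(the multiplier is capped at ``delta_max``), so the step recovers
after transients.  Negative concentrations are not clipped — the ODE
flow defines the dynamics — but an excursion below -1e-9 is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .integrators import (
    DELTA_MAX,
    NewtonConvergenceError,
    SingularMatrixError,
    StepFailureError,
    bdf_step,
    rkf_step,
    step_control,
)
from .model_io import ReactionModel, validate_model
from .ode_encoding import CompressedODESystem, build_encoding

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "Diagnostics",
    "DeviationReport",
    "SimulationError",
    "default_config",
    "simulate",
    "compare_trajectories",
]

logger = logging.getLogger(__name__)

#: relative slack used to decide that a sampling instant has been reached
_TIME_TOL = 1e-12

#: threshold below which a negative concentration excursion is logged
_NEGATIVE_WARN = -1e-9


class SimulationError(RuntimeError):
    """Numerical failure that prevents completing the simulation."""


@dataclass
class SimulationConfig:
    """Solver parameters; the defaults are the reference parameterization.

    ``eps_rkf``
        per-species tolerance on the explicit error measure ER
        (scalar broadcasts to all species); default 1e-12.
    ``bdf_order``
        BDF order q in 1..6 used in stiff phases; default 1
        (backward Euler).  Orders above 1 are ramped up one step at a
        time as uniform-spacing history accumulates.
    ``dt_bdf``
        implicit macro-step length; default 0.1.
    ``eps_nr`` / ``max_it``
        Newton-Raphson update tolerance (max-norm) and iteration cap;
        defaults 1e-6 and 10^4.
    ``dt0``
        initial explicit step-size, also restored after every stiff
        phase; default 1e-3.
    ``eps_s``
        step-size threshold below which the system is declared stiff;
        default 1e-6.
    ``delta_max`` / ``dt_max``
        growth cap of the step multiplier (default 4) and absolute
        step-size cap (default: the interval to the next sampling
        instant).
    ``recorded_species``
        optional index subset to record (default: all species, or the
        model's ``cs_vector`` hint when present).
    ``bdf_steps_per_switch``
        number of implicit macro-steps taken per stiffness switch
        before the explicit method is retried; default 1.
    ``compact_indices``
        build the encoding in 16-bit compact-validation mode.
    """

    eps_rkf: np.ndarray | float = 1e-12
    bdf_order: int = 1
    dt_bdf: float = 0.1
    eps_nr: float = 1e-6
    max_it: int = 10_000
    dt0: float = 1e-3
    eps_s: float = 1e-6
    delta_max: float = DELTA_MAX
    dt_max: float | None = None
    recorded_species: np.ndarray | None = None
    bdf_steps_per_switch: int = 1
    compact_indices: bool = False

    def validated(self) -> "SimulationConfig":
        if np.any(np.asarray(self.eps_rkf) <= 0):
            raise ValueError("eps_rkf must be positive")
        for name in ("dt_bdf", "eps_nr", "dt0", "eps_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= int(self.bdf_order) <= 6:
            raise ValueError("bdf_order must be in 1..6")
        if self.max_it < 1:
            raise ValueError("max_it must be >= 1")
        if self.bdf_steps_per_switch < 1:
            raise ValueError("bdf_steps_per_switch must be >= 1")
        return self


def default_config(n_species: int) -> SimulationConfig:
    """The reference parameterization with a length-N tolerance vector."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return SimulationConfig(eps_rkf=np.full(n_species, 1e-12))


@dataclass
class Diagnostics:
    """Step and switching counters accumulated during a run."""

    accepted_rkf: int = 0
    rejected_rkf: int = 0
    bdf_steps: int = 0
    switches: int = 0
    newton_retries: int = 0


@dataclass
class SimulationResult:
    """Sampled trajectory: times x recorded-species concentration matrix."""

    times: np.ndarray
    states: np.ndarray
    species_labels: list[str]
    diagnostics: Diagnostics = field(default_factory=Diagnostics)


def simulate(
    model: ReactionModel, config: SimulationConfig | None = None
) -> SimulationResult:
    """Integrate ``model`` and record it at every sampling instant.

    Raises :class:`SimulationError` if the implicit solver fails after
    a retry or the state becomes non-finite.
    """
    violations = validate_model(model)
    if violations:
        raise ValueError(
            "invalid model: " + "; ".join(str(v) for v in violations)
        )
    if config is None:
        config = default_config(model.n_species)
    config = config.validated()

    n = model.n_species
    eps = np.broadcast_to(
        np.asarray(config.eps_rkf, dtype=float), (n,)
    ).copy()

    recorded = config.recorded_species
    if recorded is None:
        recorded = model.recorded_species
    if recorded is None:
        recorded = np.arange(n)
    else:
        recorded = np.asarray(recorded, dtype=int)
        if recorded.size and (recorded.min() < 0 or recorded.max() >= n):
            raise ValueError("recorded species index out of range")
    all_labels = model.species_labels()
    labels = [all_labels[j] for j in recorded]

    system = build_encoding(model, compact_mode=config.compact_indices)
    times = model.sampling_times
    X = model.initial_state.astype(float).copy()
    out = np.empty((times.size, recorded.size))
    out[0] = X[recorded]
    diag = Diagnostics()

    t = float(times[0])
    dt = config.dt0
    for k in range(1, times.size):
        t_next = float(times[k])
        X, dt = _advance(system, X, t, t_next, dt, eps, config, diag)
        t = t_next
        out[k] = X[recorded]
        low = float(X.min(initial=0.0))
        if low < _NEGATIVE_WARN:
            logger.warning(
                "negative concentration %.3e at t = %g (not clipped)", low, t
            )

    return SimulationResult(
        times=times.copy(), states=out, species_labels=labels, diagnostics=diag
    )


def _advance(
    system: CompressedODESystem,
    X: np.ndarray,
    t: float,
    t_next: float,
    dt: float,
    eps: np.ndarray,
    config: SimulationConfig,
    diag: Diagnostics,
) -> tuple[np.ndarray, float]:
    """Integrate from t to t_next, landing exactly on t_next.

    The controller step-size ``dt`` persists across sampling segments;
    it is returned alongside the final state.
    """
    dt_max = config.dt_max if config.dt_max is not None else t_next - t
    dt = min(dt, dt_max)
    tol = _TIME_TOL * max(1.0, abs(t_next))
    while t_next - t > tol:
        h = min(dt, t_next - t)
        try:
            result = rkf_step(system, X, t, h, eps, config.delta_max)
            decision = step_control(result, eps, h, config.eps_s)
        except StepFailureError:
            # overflow on a wildly unstable trial step: treat as a
            # rejection with a fixed 4x shrink
            new_dt = 0.25 * h
            action = "retry" if new_dt >= config.eps_s else "switch_to_bdf"
            decision = _FailedStep(action, new_dt)
        if decision.action == "accept":
            X = decision.new_state
            t += h
            dt = min(decision.new_dt, dt_max)
            diag.accepted_rkf += 1
        elif decision.action == "retry":
            dt = decision.new_dt
            diag.rejected_rkf += 1
        else:  # stiff: implicit macro-steps, then retry explicit at dt0
            diag.rejected_rkf += 1
            diag.switches += 1
            logger.info(
                "stiffness detected at t = %g (dt would be %.3e); "
                "switching to BDF order %d",
                t,
                decision.new_dt,
                config.bdf_order,
            )
            X, t = _bdf_phase(system, X, t, t_next, config, diag)
            dt = min(config.dt0, dt_max)
        if not np.all(np.isfinite(X)):
            raise SimulationError(f"non-finite state at t = {t!r}")
    return X, dt


@dataclass
class _FailedStep:
    action: str
    new_dt: float
    new_state: np.ndarray | None = None


def _bdf_phase(
    system: CompressedODESystem,
    X: np.ndarray,
    t: float,
    t_next: float,
    config: SimulationConfig,
    diag: Diagnostics,
) -> tuple[np.ndarray, float]:
    """Take up to ``bdf_steps_per_switch`` implicit macro-steps.

    The order is ramped up from 1 towards ``bdf_order`` as uniformly
    spaced history accumulates; a change of the (clamped) macro-step
    length resets the history to order 1.  A Newton failure is retried
    once at a tenfold smaller step before the run is aborted.
    """
    history: list[np.ndarray] = [X]
    spacing: float | None = None
    tol = _TIME_TOL * max(1.0, abs(t_next))
    for _ in range(config.bdf_steps_per_switch):
        h = min(config.dt_bdf, t_next - t)
        if h <= tol:
            break
        if spacing is not None and not np.isclose(h, spacing, rtol=1e-12):
            history = [history[-1]]
        q_eff = min(config.bdf_order, len(history))
        try:
            X_new = bdf_step(
                system, history, h, q_eff, config.eps_nr, config.max_it
            )
        except (NewtonConvergenceError, SingularMatrixError):
            diag.newton_retries += 1
            h = h / 10.0
            history = [history[-1]]
            try:
                X_new = bdf_step(
                    system, history, h, 1, config.eps_nr, config.max_it
                )
            except (NewtonConvergenceError, SingularMatrixError) as exc:
                raise SimulationError(
                    f"implicit solver failed at t = {t!r} "
                    f"(after step retry at dt = {h!r}): {exc}"
                ) from exc
        if not np.all(np.isfinite(X_new)):
            raise SimulationError(f"non-finite implicit step at t = {t!r}")
        t += h
        spacing = h
        history.append(X_new)
        if len(history) > config.bdf_order:
            history = history[-config.bdf_order:]
        X = X_new
        diag.bdf_steps += 1
    return X, t


@dataclass
class DeviationReport:
    """Largest absolute and relative deviation between two trajectories."""

    max_abs: float
    max_abs_location: tuple[float, str]
    max_rel: float
    max_rel_location: tuple[float, str]
    within_tolerance: bool


def compare_trajectories(
    a: SimulationResult,
    b: SimulationResult,
    rtol: float = 1e-4,
    atol: float = 1e-8,
) -> DeviationReport:
    """Compare two sampled trajectories on identical grids.

    The relative deviation uses ``b`` as the reference with absolute
    floor ``atol``: ``|a - b| / max(|b|, atol)``.  Raises ``ValueError``
    on mismatched time grids or species sets.
    """
    if not np.array_equal(a.times, b.times):
        raise ValueError("time grids differ")
    if list(a.species_labels) != list(b.species_labels):
        raise ValueError("species sets differ")
    if a.states.shape != b.states.shape:
        raise ValueError("state matrices differ in shape")
    diff = np.abs(a.states - b.states)
    rel = diff / np.maximum(np.abs(b.states), atol)

    def _loc(matrix: np.ndarray) -> tuple[float, str]:
        i, j = np.unravel_index(int(np.argmax(matrix)), matrix.shape)
        return float(a.times[i]), a.species_labels[j]

    max_abs = float(diff.max(initial=0.0))
    max_rel = float(rel.max(initial=0.0))
    return DeviationReport(
        max_abs=max_abs,
        max_abs_location=_loc(diff) if diff.size else (float("nan"), ""),
        max_rel=max_rel,
        max_rel_location=_loc(rel) if rel.size else (float("nan"), ""),
        within_tolerance=bool(max_rel <= rtol),
    )
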
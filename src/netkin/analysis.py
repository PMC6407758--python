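"""Post-processing and model interrogation.

Steady-state plateau detection on trajectories, the algebraic steady-state
approximation (SSA: set d[intermediate]/dt = 0 and solve), full-integration
vs SSA validity reports, phase-space extraction and a largest-Lyapunov-
exponent estimator for chaos diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import BlowupError, ConvergenceError, InvalidParameterError
from .network import compile_rhs
from .scheme import KineticScheme
from .solver import SimulationOptions, Trajectory, integrate

__all__ = [
    "SteadyStateResult",
    "SSAResult",
    "SSAComparison",
    "LyapunovResult",
    "steady_state",
    "ssa_solve",
    "compare_ssa",
    "phase_space",
    "lyapunov_max",
    "conservation_laws",
]


@dataclass(frozen=True)
class SteadyStateResult:
    """Plateau of a trajectory: values at the final time, detection flag,
    the earliest time from which the trajectory stays flat, and the
    relative-change-per-print-step criterion used."""

    values: np.ndarray
    reached: bool
    detection_time: float | None
    criterion: float
    species: tuple[str, ...] | None = None


def steady_state(
    trajectory: Trajectory, rel_threshold: float = 1e-6
) -> SteadyStateResult:
    """Detect a stationary plateau on the print grid.

    The plateau is the earliest print point after which every species'
    change per print step stays below ``rel_threshold``, relative to that
    species' amplitude over the whole trajectory (an amplitude-relative
    criterion: species that decay exactly to zero still plateau). Values are
    taken at the final time. Never raises; ``reached`` is False when no
    plateau exists.
    """
    states = np.asarray(trajectory.states)
    times = np.asarray(trajectory.times)
    if states.shape[0] < 2:
        return SteadyStateResult(
            values=states[-1].copy(),
            reached=True,
            detection_time=float(times[0]) if len(times) else 0.0,
            criterion=rel_threshold,
            species=trajectory.species,
        )
    scale = np.maximum(np.max(np.abs(states), axis=0), 1e-300)
    rel_change = np.abs(np.diff(states, axis=0)) / scale[None, :]
    flat = np.all(rel_change < rel_threshold, axis=1)  # per interval
    # earliest index i such that flat[i:] is all True
    not_flat = np.nonzero(~flat)[0]
    if not_flat.size == 0:
        start = 0
    elif not_flat[-1] == flat.size - 1:
        return SteadyStateResult(
            values=states[-1].copy(),
            reached=False,
            detection_time=None,
            criterion=rel_threshold,
            species=trajectory.species,
        )
    else:
        start = not_flat[-1] + 1
    return SteadyStateResult(
        values=states[-1].copy(),
        reached=True,
        detection_time=float(times[start]),
        criterion=rel_threshold,
        species=trajectory.species,
    )


@dataclass(frozen=True)
class SSAResult:
    """Solution of the hybrid algebraic system d[x]/dt = 0 for the
    intermediates, with the remaining species clamped."""

    values: np.ndarray
    intermediates: frozenset[str]
    residual: float
    species: tuple[str, ...]


def ssa_solve(
    scheme: KineticScheme,
    intermediates,
    x_fixed: dict[str, float] | None = None,
    *,
    residual_tol: float = 1e-10,
    rel_residual_tol: float = 1e-8,
    max_iter: int = 200,
) -> SSAResult:
    """Steady-state approximation: solve rhs_i(x) = 0 for the intermediates.

    The non-intermediate species are clamped at ``x_fixed`` (default: the
    scheme's initial concentrations). The algebraic system is solved by
    damped Newton from the scheme's initial guess, with ten log-spaced
    positive restarts on failure. Convergence demands the residual below
    ``residual_tol`` *and* below ``rel_residual_tol`` times the largest
    individual mass-action addend at the root — the relative condition keeps
    near-cancelling systems with tiny absolute rates honest. Raises
    :class:`ConvergenceError` (carrying the best residual) if no root is
    found.
    """
    intermediates = frozenset(intermediates)
    names = scheme.species_names
    if not intermediates:
        raise InvalidParameterError("intermediates must be non-empty")
    unknown = intermediates - set(names)
    if unknown:
        raise InvalidParameterError(f"unknown intermediates {sorted(unknown)}")
    if intermediates == set(names):
        raise InvalidParameterError(
            "intermediates must be a strict subset of the species"
        )
    rhs = compile_rhs(scheme)
    x = scheme.initial_state()
    if x_fixed:
        for name, value in x_fixed.items():
            x[scheme.species_index(name)] = value
    idx = np.array([i for i, n in enumerate(names) if n in intermediates])

    def residual_vec(u):
        state = x.copy()
        state[idx] = u
        return np.asarray(rhs(0.0, state))[idx]

    def jac_sub(u):
        state = x.copy()
        state[idx] = u
        return rhs.jacobian(0.0, state)[np.ix_(idx, idx)]

    coef, expo, target = rhs.term_arrays
    in_subsystem = np.isin(target, idx)

    def addend_scale(u):
        state = x.copy()
        state[idx] = u
        mags = np.abs(coef) * np.prod(
            np.power(np.abs(state)[None, :], expo), axis=1
        )
        return float(np.max(mags[in_subsystem])) if in_subsystem.any() else 0.0

    def converged(u, rnorm):
        return rnorm <= residual_tol and \
            rnorm <= rel_residual_tol * max(addend_scale(u), 1e-300)

    scale = max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    starts = [x[idx].copy()]
    starts += [np.full(idx.size, scale * s) for s in np.logspace(-10, 1, 10)]

    best_residual = math.inf
    for u0 in starts:
        u = np.asarray(u0, dtype=float).copy()
        r = residual_vec(u)
        rnorm = float(np.max(np.abs(r)))
        ok = True
        for _ in range(max_iter):
            if not np.all(np.isfinite(r)):
                ok = False
                break
            try:
                delta = np.linalg.solve(jac_sub(u), -r)
            except np.linalg.LinAlgError:
                ok = False
                break
            lam = 1.0
            improved = False
            for _ in range(30):  # damping: backtrack until the residual drops
                trial = u + lam * delta
                r_trial = residual_vec(trial)
                if np.all(np.isfinite(r_trial)) and \
                        float(np.max(np.abs(r_trial))) < rnorm:
                    u, r = trial, r_trial
                    rnorm = float(np.max(np.abs(r)))
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
            if converged(u, rnorm) or np.max(
                np.abs(lam * delta) / np.maximum(np.abs(u), 1e-300)
            ) < 1e-15:
                break
        best_residual = min(best_residual, rnorm)
        if ok and converged(u, rnorm):
            values = x.copy()
            values[idx] = u
            return SSAResult(
                values=values,
                intermediates=intermediates,
                residual=rnorm,
                species=names,
            )
    raise ConvergenceError(
        "steady-state approximation solve did not converge",
        best_residual=best_residual,
    )


@dataclass(frozen=True)
class SSAComparison:
    """Full-integration plateau vs SSA solution, per-species ratio."""

    species: tuple[str, ...]
    intermediates: frozenset[str]
    full_values: np.ndarray
    ssa_values: np.ndarray
    ratios: dict[str, float]
    valid: dict[str, bool]
    validity_factor: float
    steady: SteadyStateResult
    ssa: SSAResult

    def as_text(self) -> str:
        lines = [
            "species  full-integration  SSA            ratio     verdict",
        ]
        for name in self.species:
            if name not in self.intermediates:
                continue
            i = self.species.index(name)
            verdict = "ok" if self.valid[name] else "SSA-invalid"
            lines.append(
                f"{name:<8} {self.full_values[i]:<17.6g} "
                f"{self.ssa_values[i]:<14.6g} {self.ratios[name]:<9.4g} "
                f"{verdict}"
            )
        return "\n".join(lines)

    def to_csv(self) -> str:
        lines = ["species,full,ssa,ratio,valid"]
        for name in self.species:
            if name not in self.intermediates:
                continue
            i = self.species.index(name)
            lines.append(
                f"{name},{self.full_values[i]:.10g},"
                f"{self.ssa_values[i]:.10g},{self.ratios[name]:.10g},"
                f"{int(self.valid[name])}"
            )
        return "\n".join(lines) + "\n"


def compare_ssa(
    scheme: KineticScheme,
    intermediates,
    options: SimulationOptions,
    *,
    rel_threshold: float = 1e-6,
    validity_factor: float = 2.0,
) -> SSAComparison:
    """Test the steady-state approximation against full integration.

    Integrates the complete scheme to its plateau, solves the SSA system
    with the non-intermediates clamped at their initial concentrations, and
    reports the per-intermediate ratio full/SSA. A species is flagged
    SSA-invalid when its ratio deviates from 1 by more than
    ``validity_factor`` (in either direction). The comparison is meaningful
    on horizons over which the clamped species stay close to their initial
    values — exactly the regime in which the approximation claims validity.
    """
    intermediates = frozenset(intermediates)
    rhs = compile_rhs(scheme)
    trajectory = integrate(rhs, scheme.initial_state(), options)
    steady = steady_state(trajectory, rel_threshold)
    ssa = ssa_solve(scheme, intermediates)
    names = scheme.species_names
    ratios = {}
    valid = {}
    for name in names:
        if name not in intermediates:
            continue
        i = names.index(name)
        denom = ssa.values[i]
        ratio = math.inf if denom == 0 else float(steady.values[i] / denom)
        ratios[name] = ratio
        spread = max(abs(ratio), 1 / abs(ratio)) if ratio > 0 else math.inf
        valid[name] = spread <= validity_factor
    return SSAComparison(
        species=names,
        intermediates=intermediates,
        full_values=steady.values,
        ssa_values=ssa.values,
        ratios=ratios,
        valid=valid,
        validity_factor=validity_factor,
        steady=steady,
        ssa=ssa,
    )


def phase_space(trajectory: Trajectory, species_triple) -> np.ndarray:
    """Ordered (n_times, 3) point list of three species' concentrations."""
    names = tuple(species_triple)
    if len(names) != 3:
        raise InvalidParameterError("phase_space needs exactly three species")
    return np.column_stack([trajectory.column(n) for n in names])


@dataclass(frozen=True)
class LyapunovResult:
    """Largest-Lyapunov-exponent estimate (1/time units of the model)."""

    estimate: float
    stderr: float
    n_segments: int
    renorm_interval: float
    log_stretches: np.ndarray = field(repr=False, default=None)


def lyapunov_max(
    rhs,
    x0,
    horizon: float,
    renorm_interval: float = 1.0,
    *,
    perturbation: float | None = None,
    reltol: float = 1e-8,
    escape_factor: float = 1e6,
    integrator: str = "adaptive",
    dt: float = 1e-3,
) -> LyapunovResult:
    """Largest Lyapunov exponent by the Benettin two-trajectory method.

    A companion trajectory displaced by ``perturbation`` (default
    1e-8 * ||x0||, floored at 1e-8) is integrated alongside the reference;
    at every ``renorm_interval`` the separation is measured, its log stretch
    recorded, and the companion renormalised back to the reference distance.
    The exponent is the mean log stretch per unit time over the second half
    of the run (the first half is discarded as transient), with the standard
    error of that mean. Raises :class:`BlowupError` if the trajectory
    escapes (norm grows by ``escape_factor`` over the initial norm).

    ``integrator`` selects how the segments are propagated: ``"adaptive"``
    (the native implicit engine at ``reltol``) or ``"rk4"`` (fixed-step
    classical Runge-Kutta at step ``dt``, using the compiled term arrays
    when the rhs carries them — the economical choice for the long horizons
    chaotic attractors need).
    """
    x = np.asarray(x0, dtype=float).copy()
    if perturbation is None:
        perturbation = 1e-8 * max(float(np.linalg.norm(x)), 1.0)
    n_segments = int(round(horizon / renorm_interval))
    if n_segments < 4:
        raise InvalidParameterError(
            "horizon must cover at least four renormalisation intervals"
        )
    if integrator not in ("adaptive", "rk4"):
        raise InvalidParameterError(
            f"integrator must be 'adaptive' or 'rk4', got {integrator!r}"
        )
    direction = np.ones_like(x) / math.sqrt(x.size)
    y = x + perturbation * direction
    scale0 = max(float(np.linalg.norm(x)), 1.0)
    options = SimulationOptions(
        total_time=renorm_interval,
        print_step=renorm_interval,
        reltol=reltol,
    )
    if integrator == "rk4":
        from .oracle import rk4, rk4_mass_action

        n_steps = max(2, int(round(renorm_interval / dt)))
        arrays = getattr(rhs, "term_arrays", None)
        if arrays is not None:
            def advance(state):
                _, states = rk4_mass_action(
                    *arrays, state, renorm_interval, n_steps, n_save=2
                )
                return states[-1]
        else:
            def advance(state):
                _, states = rk4(rhs, state, renorm_interval, n_steps, n_save=2)
                return states[-1]
    else:
        def advance(state):
            return integrate(rhs, state, options).final_state

    stretches = np.empty(n_segments)
    for seg in range(n_segments):
        x = advance(x)
        y = advance(y)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise BlowupError("trajectory became non-finite",
                              seg * renorm_interval)
        if float(np.linalg.norm(x)) > escape_factor * scale0:
            raise BlowupError("trajectory escaped", seg * renorm_interval)
        d = float(np.linalg.norm(y - x))
        if d == 0.0:
            d = 1e-300
        stretches[seg] = math.log(d / perturbation)
        y = x + (perturbation / d) * (y - x)
    tail = stretches[n_segments // 2:]
    rates = tail / renorm_interval
    estimate = float(np.mean(rates))
    stderr = float(np.std(rates, ddof=1) / math.sqrt(rates.size))
    return LyapunovResult(
        estimate=estimate,
        stderr=stderr,
        n_segments=n_segments,
        renorm_interval=renorm_interval,
        log_stretches=stretches,
    )


def conservation_laws(scheme: KineticScheme) -> np.ndarray:
    """Orthonormal basis of linear conserved quantities w (w . x is constant).

    A weight vector w is conserved iff w . dx/dt vanishes identically in the
    concentrations. Because the right-hand sides are signed mass-action
    polynomials, it suffices that for every distinct monomial (rate constant
    + exponent pattern) the signed multipliers across equations cancel under
    w. Returns an (n_species, n_laws) array (possibly empty).
    """
    names = scheme.species_names
    index = {n: i for i, n in enumerate(names)}
    groups: dict[tuple, np.ndarray] = {}
    for name in names:
        for term in scheme.equation(name).terms:
            key = (term.constant, tuple(sorted(term.factors)))
            row = groups.setdefault(key, np.zeros(len(names)))
            row[index[name]] += term.sign * term.multiplier
    if not groups:
        return np.eye(len(names))
    matrix = np.vstack(list(groups.values()))
    return scipy.linalg.null_space(matrix)
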
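"""Native variable-step implicit integrator (trapezoidal + 2nd-order Gear).

The transient engine mirrors the classic SPICE scheme: an A-stable pair of
second-order implicit rules — the trapezoidal rule, with variable-coefficient
BDF2 ("Gear-2") as companion — driven by a local-truncation-error controller
keyed to RELTOL. Each step solves the implicit update by Newton iteration on
the analytic mass-action Jacobian when available, else on central finite
differences.

Policy (``method="tr-gear"``, the default): integrate with trapezoidal
steps; when the per-component truncation-error estimate starts alternating
in sign between consecutive accepted steps (trapezoidal ringing on stiff
components), fall back to BDF2 for a while. Pure ``"trapezoidal"`` and
``"gear2"`` modes are selectable for testing. The very first step is a
backward-Euler (BDF1) step that seeds the BDF2 history.

Accepted-step results live on an irregular mesh; output is interpolated onto
the regular print grid with cubic Hermite polynomials, so printing never
constrains the adaptive mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import BlowupError, InvalidParameterError, StiffnessError
from .scheme import KineticScheme

__all__ = [
    "SimulationOptions",
    "Trajectory",
    "integrate",
    "step_trapezoidal",
    "step_gear2",
    "step_backward_euler",
    "jacobian",
]

_METHODS = ("trapezoidal", "gear2", "tr-gear")

# step-size controller constants (2nd-order rule => 1/3 exponent)
_SAFETY = 0.9
_GROW_MAX = 5.0
_SHRINK_MIN = 0.2
_RINGING_STEPS = 20  # BDF2 steps taken after ringing is detected

# Per-step truncation errors accumulate over the run, so the controller
# accepts steps against reltol scaled by this margin; it keeps the realised
# global error of smooth problems within a small multiple of reltol.
_TOL_MARGIN = 0.1


@dataclass(frozen=True)
class SimulationOptions:
    """Transient-analysis options.

    ``total_time`` (s) is the simulated horizon; ``print_step`` (s) the
    spacing of the output grid; ``reltol`` the relative truncation-error
    tolerance of the step controller; ``numdgt`` the number of significant
    digits used for text output (formatting only, never arithmetic);
    ``abstol`` an absolute error floor (mol/l) that keeps the controller
    sane near zero concentrations.
    """

    total_time: float
    print_step: float | None = None
    reltol: float = 1e-3
    numdgt: int = 6
    abstol: float = 1e-12
    method: str = "tr-gear"
    max_step: float | None = None
    min_step: float | None = None
    initial_step: float | None = None
    newton_tol: float = 1e-2
    newton_max_iter: int = 12
    seed: int | None = None  # unused; kept for API stability

    def resolved(self) -> "SimulationOptions":
        """Fill derived defaults and check all invariants."""
        if not (self.total_time > 0) or not math.isfinite(self.total_time):
            raise InvalidParameterError(
                f"total_time must be positive, got {self.total_time!r}"
            )
        print_step = self.print_step
        if print_step is None:
            print_step = self.total_time / 200.0
        if not (0 < print_step <= self.total_time):
            raise InvalidParameterError(
                f"print_step must lie in (0, total_time], got {print_step!r}"
            )
        if not (0 < self.reltol <= 0.1):
            raise InvalidParameterError(
                f"reltol must lie in (0, 0.1], got {self.reltol!r}"
            )
        if self.abstol < 0:
            raise InvalidParameterError("abstol must be non-negative")
        if self.method not in _METHODS:
            raise InvalidParameterError(
                f"method must be one of {_METHODS}, got {self.method!r}"
            )
        if self.numdgt < 1:
            raise InvalidParameterError("numdgt must be at least 1")
        max_step = self.max_step if self.max_step is not None \
            else self.total_time / 10.0
        initial_step = self.initial_step if self.initial_step is not None \
            else min(print_step * 1e-6, max_step)
        min_step = self.min_step if self.min_step is not None \
            else self.total_time * 1e-16
        if not (min_step < initial_step <= max_step):
            raise InvalidParameterError(
                f"need min_step < initial_step <= max_step, got "
                f"{min_step!r}, {initial_step!r}, {max_step!r}"
            )
        return replace(
            self,
            print_step=print_step,
            max_step=max_step,
            min_step=min_step,
            initial_step=initial_step,
        )


@dataclass
class Trajectory:
    """Concentrations on the regular print grid, plus run statistics."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def column(self, name: str) -> np.ndarray:
        if self.species is None:
            raise KeyError("trajectory carries no species names")
        try:
            return self.states[:, self.species.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def to_csv(self, numdgt: int = 6) -> str:
        """RFC-4180 CSV text, values to ``numdgt`` significant digits."""
        names = self.species or tuple(
            f"x{i}" for i in range(self.states.shape[1])
        )
        lines = ["t," + ",".join(names)]
        for t, row in zip(self.times, self.states):
            lines.append(
                f"{t:.{numdgt}g}," + ",".join(f"{v:.{numdgt}g}" for v in row)
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def jacobian(rhs, x, t: float = 0.0, rel_step: float = 1e-6) -> np.ndarray:
    """Jacobian of a right-hand side at state ``x``.

    A :class:`KineticScheme` (or a compiled rhs carrying ``.jacobian``) gets
    exact partial derivatives of its mass-action polynomial; any other
    callable is differenced centrally with steps scaled by ``rel_step``.
    """
    if isinstance(rhs, KineticScheme):
        from .network import compile_rhs

        return compile_rhs(rhs).jacobian(t, np.asarray(x, dtype=float))
    if hasattr(rhs, "jacobian"):
        return np.asarray(rhs.jacobian(t, np.asarray(x, dtype=float)))
    return _fd_jacobian(rhs, t, np.asarray(x, dtype=float), rel_step)


def _fd_jacobian(f, t, x, rel_step=1e-6):
    n = x.size
    jac = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (np.asarray(f(t, xp)) - np.asarray(f(t, xm))) / (2 * h)
    return jac


def _jac_of(rhs, jac):
    if jac is not None:
        return jac
    if hasattr(rhs, "jacobian"):
        return rhs.jacobian
    return lambda t, x: _fd_jacobian(rhs, t, x)


class _NewtonFailure(Exception):
    """Internal step-reject signal."""


def _newton(residual, jac_of_y, y0, weights, tol, max_iter):
    """Damped-free Newton for the implicit step equations.

    ``residual(y)`` and ``jac_of_y(y)`` define g(y) = 0; convergence when the
    weighted update norm drops below ``tol``. Raises _NewtonFailure on
    divergence, singularity or non-finite values.
    """
    y = y0.copy()
    n_iter = 0
    for _ in range(max_iter):
        g = residual(y)
        if not np.all(np.isfinite(g)):
            raise _NewtonFailure
        try:
            delta = np.linalg.solve(jac_of_y(y), -g)
        except np.linalg.LinAlgError:
            raise _NewtonFailure from None
        y = y + delta
        n_iter += 1
        if not np.all(np.isfinite(y)):
            raise _NewtonFailure
        if np.max(np.abs(delta) / weights) <= tol or np.max(
            np.abs(delta)
        ) <= 4e-16 * np.max(np.abs(y)):  # machine-precision floor
            return y, n_iter
    raise _NewtonFailure


def _weights(x, reltol, abstol):
    return reltol * np.maximum(np.abs(x), 1e-300) + abstol


# ---------------------------------------------------------------------------
# Single steps
# ---------------------------------------------------------------------------

def step_trapezoidal(
    rhs,
    x,
    t,
    h,
    *,
    jac=None,
    f0=None,
    reltol: float = 1e-6,
    abstol: float = 1e-12,
    newton_tol: float = 1e-2,
    newton_max_iter: int = 12,
):
    """One trapezoidal step: solve x1 = x + (h/2)(f(t,x) + f(t+h,x1)).

    Returns ``(x1, lte, info)`` where ``lte`` estimates the local truncation
    error -(h^3/12) x''' from the divided difference of f across the step
    (one extra midpoint evaluation), and ``info`` holds Newton statistics.
    Raises an internal reject signal on Newton non-convergence — callers
    inside :func:`integrate` retry with a smaller step.
    """
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = np.asarray(rhs(t, x))
    jac_f = _jac_of(rhs, jac)
    eye = np.eye(x.size)
    w = _weights(x, reltol, abstol)

    def residual(y):
        return y - x - 0.5 * h * (f0 + np.asarray(rhs(t + h, y)))

    def gprime(y):
        return eye - 0.5 * h * np.asarray(jac_f(t + h, y))

    y, n_newton = _newton(
        residual, gprime, x + h * f0, w, newton_tol, newton_max_iter
    )
    f1 = np.asarray(rhs(t + h, y))
    # Hermite midpoint of the step, then second divided difference of f:
    # f0 - 2 f(mid) + f1 ~ (h^2/4) x''', so lte ~ h^3 x'''/12 within O(1).
    xm = 0.5 * (x + y) + 0.125 * h * (f0 - f1)
    fm = np.asarray(rhs(t + 0.5 * h, xm))
    lte = h * (f0 - 2.0 * fm + f1) / 3.0
    return y, lte, {"newton_iterations": n_newton, "f_end": f1}


def step_gear2(
    rhs,
    x_prev,
    x,
    t,
    h,
    *,
    h_prev=None,
    jac=None,
    f0=None,
    reltol: float = 1e-6,
    abstol: float = 1e-12,
    newton_tol: float = 1e-2,
    newton_max_iter: int = 12,
):
    """One variable-coefficient BDF2 ("Gear-2") step.

    With step ratio rho = h/h_prev the update solves

        x1 = (1+rho)^2/(1+2 rho) x - rho^2/(1+2 rho) x_prev
             + h (1+rho)/(1+2 rho) f(t+h, x1),

    which reduces to x1 = (4x - x_prev)/3 + (2h/3) f(t+h, x1) at constant
    step. The truncation-error estimate is the scaled difference between the
    corrector and a quadratic predictor through (t-h_prev, x_prev) and
    (t, x, f(t,x)).
    """
    x = np.asarray(x, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    if h_prev is None:
        h_prev = h
    if f0 is None:
        f0 = np.asarray(rhs(t, x))
    rho = h / h_prev
    a1 = (1 + rho) ** 2 / (1 + 2 * rho)
    a2 = -(rho ** 2) / (1 + 2 * rho)
    b = (1 + rho) / (1 + 2 * rho)
    jac_f = _jac_of(rhs, jac)
    eye = np.eye(x.size)
    w = _weights(x, reltol, abstol)
    hist = a1 * x + a2 * x_prev

    def residual(y):
        return y - hist - b * h * np.asarray(rhs(t + h, y))

    def gprime(y):
        return eye - b * h * np.asarray(jac_f(t + h, y))

    # quadratic predictor q(s): q(0)=x, q'(0)=f0, q(-h_prev)=x_prev
    c2 = (x_prev - x + h_prev * f0) / h_prev ** 2
    predictor = x + h * f0 + c2 * h ** 2
    y, n_newton = _newton(
        residual, gprime, predictor, w, newton_tol, newton_max_iter
    )
    lte = 0.4 * (y - predictor)  # both O(h^3 x'''); 0.4 matches the
    # constant-step ratio of the corrector's -(2/9)h^3 x''' truncation error
    # to the predictor-corrector gap
    f1 = np.asarray(rhs(t + h, y))
    return y, lte, {"newton_iterations": n_newton, "f_end": f1}


def step_backward_euler(
    rhs,
    x,
    t,
    h,
    *,
    jac=None,
    f0=None,
    reltol: float = 1e-6,
    abstol: float = 1e-12,
    newton_tol: float = 1e-2,
    newton_max_iter: int = 12,
):
    """One backward-Euler (BDF1) step; used only to seed the history."""
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = np.asarray(rhs(t, x))
    jac_f = _jac_of(rhs, jac)
    eye = np.eye(x.size)
    w = _weights(x, reltol, abstol)

    def residual(y):
        return y - x - h * np.asarray(rhs(t + h, y))

    def gprime(y):
        return eye - h * np.asarray(jac_f(t + h, y))

    y, n_newton = _newton(
        residual, gprime, x + h * f0, w, newton_tol, newton_max_iter
    )
    f1 = np.asarray(rhs(t + h, y))
    lte = y - x - h * f0  # ~ (h^2/2) x''
    return y, lte, {"newton_iterations": n_newton, "f_end": f1}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _hermite_eval(t_star, t0, t1, x0, x1, f0, f1):
    h = t1 - t0
    s = (t_star - t0) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s ** 2 * (3 - 2 * s)
    h11 = s ** 2 * (s - 1)
    return h00 * x0 + h10 * h * f0 + h01 * x1 + h11 * h * f1


def integrate(
    rhs,
    x0,
    options: SimulationOptions,
    *,
    species: Sequence[str] | None = None,
    jac=None,
) -> Trajectory:
    """Integrate ``dx/dt = rhs(t, x)`` from ``x0`` over the options' horizon.

    ``rhs`` may be a compiled mass-action evaluator (from
    :func:`netkin.network.compile_rhs`; its analytic Jacobian is then used by
    the Newton iterations) or any plain callable (finite-difference
    Jacobian). Raises :class:`StiffnessError` when the step size underflows
    and :class:`BlowupError` when the state leaves the finite range.

    Concentrations are *not* clamped at zero: tolerance-level undershoot is
    reported as computed, never corrected.
    """
    opts = options.resolved()
    x = np.asarray(x0, dtype=float).copy()
    if x.ndim != 1:
        raise InvalidParameterError("x0 must be a one-dimensional vector")
    if not np.all(np.isfinite(np.asarray(rhs(0.0, x)))):
        raise BlowupError("right-hand side is not finite at the initial state", 0.0)
    if species is None and hasattr(rhs, "species"):
        species = rhs.species

    jac_f = _jac_of(rhs, jac)
    stats = {
        "accepted": 0,
        "rejected": 0,
        "newton_failures": 0,
        "newton_iterations": 0,
        "method_counts": {"backward_euler": 0, "trapezoidal": 0, "gear2": 0},
        "ringing_switches": 0,
    }
    step_kwargs = dict(
        jac=jac_f,
        reltol=opts.reltol,
        abstol=opts.abstol,
        newton_tol=opts.newton_tol,
        newton_max_iter=opts.newton_max_iter,
    )

    t = 0.0
    f = np.asarray(rhs(t, x))
    mesh_t = [t]
    mesh_x = [x.copy()]
    mesh_f = [f.copy()]
    h = opts.initial_step
    h_prev = None
    x_prev = None
    lte_prev = None
    gear_countdown = 0
    consecutive_rejects = 0
    max_total_steps = 5_000_000

    while t < opts.total_time * (1 - 1e-14):
        if stats["accepted"] + stats["rejected"] > max_total_steps:
            raise StiffnessError("step budget exhausted", t)
        h = min(h, opts.max_step, opts.total_time - t)
        if h < opts.min_step:
            raise StiffnessError("step size underflow", t)

        if opts.method == "gear2" and x_prev is None:
            method = "backward_euler"
        elif opts.method == "gear2":
            method = "gear2"
        elif opts.method == "trapezoidal":
            method = "trapezoidal"
        else:  # tr-gear policy
            if x_prev is None:
                method = "backward_euler"
            elif gear_countdown > 0:
                method = "gear2"
            else:
                method = "trapezoidal"

        try:
            if method == "backward_euler":
                y, lte, info = step_backward_euler(rhs, x, t, h, f0=f, **step_kwargs)
            elif method == "trapezoidal":
                y, lte, info = step_trapezoidal(rhs, x, t, h, f0=f, **step_kwargs)
            else:
                y, lte, info = step_gear2(
                    rhs, x_prev, x, t, h, h_prev=h_prev, f0=f, **step_kwargs
                )
        except _NewtonFailure:
            stats["newton_failures"] += 1
            stats["rejected"] += 1
            consecutive_rejects += 1
            h *= 0.25 if consecutive_rejects >= 2 else 0.5
            continue

        stats["newton_iterations"] += info["newton_iterations"]
        if not np.all(np.isfinite(y)):
            raise BlowupError("state became non-finite", t)
        tol = _TOL_MARGIN * _weights(
            np.maximum(np.abs(x), np.abs(y)), opts.reltol, opts.abstol
        )
        err_norm = float(np.max(np.abs(lte) / tol))

        if err_norm <= 1.0 or h <= opts.min_step * 2:
            # accept
            f_end = info["f_end"]
            if not np.all(np.isfinite(f_end)):
                raise BlowupError("right-hand side became non-finite", t + h)
            if method == "trapezoidal" and lte_prev is not None:
                sig = (np.abs(lte) > 1e-3 * tol) & (np.abs(lte_prev) > 1e-3 * tol)
                if np.any(sig) and np.all(lte[sig] * lte_prev[sig] < 0):
                    gear_countdown = _RINGING_STEPS
                    stats["ringing_switches"] += 1
            if method == "gear2" and gear_countdown > 0:
                gear_countdown -= 1
            x_prev, h_prev = x, h
            t, x, f = t + h, y, f_end
            lte_prev = lte
            mesh_t.append(t)
            mesh_x.append(x.copy())
            mesh_f.append(f.copy())
            stats["accepted"] += 1
            stats["method_counts"][method] += 1
            consecutive_rejects = 0
            factor = _GROW_MAX if err_norm == 0.0 else min(
                _GROW_MAX, max(_SHRINK_MIN, _SAFETY * err_norm ** (-1.0 / 3.0))
            )
            h = h * factor
        else:
            stats["rejected"] += 1
            consecutive_rejects += 1
            factor = max(_SHRINK_MIN, _SAFETY * err_norm ** (-1.0 / 3.0))
            if consecutive_rejects >= 2:
                factor = min(factor, 0.5)
            h = h * factor

    # ---- interpolate onto the print grid ------------------------------
    n_print = int(round(opts.total_time / opts.print_step))
    times = np.linspace(0.0, opts.total_time, n_print + 1)
    mesh_t_arr = np.asarray(mesh_t)
    states = np.empty((times.size, x.size))
    idx = np.searchsorted(mesh_t_arr, times, side="right") - 1
    idx = np.clip(idx, 0, len(mesh_t) - 2)
    for i, t_star in enumerate(times):
        j = idx[i]
        if t_star >= mesh_t_arr[-1]:
            states[i] = mesh_x[-1]
        elif t_star <= mesh_t_arr[j] and t_star == mesh_t_arr[j]:
            states[i] = mesh_x[j]
        else:
            states[i] = _hermite_eval(
                t_star,
                mesh_t_arr[j],
                mesh_t_arr[j + 1],
                mesh_x[j],
                mesh_x[j + 1],
                mesh_f[j],
                mesh_f[j + 1],
            )

    meta = dict(stats)
    meta["options"] = opts
    meta["mesh_size"] = len(mesh_t)
    return Trajectory(
        times=times,
        states=states,
        species=tuple(species) if species is not None else None,
        meta=meta,
    )
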
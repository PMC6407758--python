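"""Brute-force cross-check integrator: classical fixed-step RK4.

This module exists to validate the native implicit engine, never to replace
it. It is deliberately an independent code path: the mass-action right-hand
side is re-evaluated here from the raw term arrays with explicit loops
(numba-compiled so that 10^6-step reference runs stay cheap), not through
the compiled evaluator the solver uses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rk4", "rk4_mass_action"]

_KERNEL = None


def rk4(rhs, x0, t_end: float, n_steps: int, n_save: int = 101):
    """Classical 4th-order Runge-Kutta at fixed step h = t_end / n_steps.

    Returns ``(times, states)`` with ``n_save`` evenly spaced samples
    (including both endpoints). Pure-python reference path for arbitrary
    right-hand sides.
    """
    x = np.asarray(x0, dtype=float).copy()
    h = t_end / n_steps
    save_every = max(1, n_steps // (n_save - 1))
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for i in range(1, n_steps + 1):
        k1 = np.asarray(rhs(t, x))
        k2 = np.asarray(rhs(t + 0.5 * h, x + 0.5 * h * k1))
        k3 = np.asarray(rhs(t + 0.5 * h, x + 0.5 * h * k2))
        k4 = np.asarray(rhs(t + h, x + h * k3))
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = i * h
        if i % save_every == 0 or i == n_steps:
            times.append(t)
            states.append(x.copy())
    return np.asarray(times), np.asarray(states)


def _kernel():
    """Compile (once) the numba RK4 kernel over raw term arrays."""
    global _KERNEL
    if _KERNEL is None:
        from numba import njit

        @njit(cache=False)
        def rhs_terms(coef, expo, target, x, out):
            out[:] = 0.0
            for tr in range(coef.size):
                r = coef[tr]
                for j in range(x.size):
                    a = expo[tr, j]
                    if a == 1.0:
                        r *= x[j]
                    elif a != 0.0:
                        r *= x[j] ** a
                out[target[tr]] += r

        @njit(cache=False)
        def run(coef, expo, target, x0, t_end, n_steps, save_every, states):
            n = x0.size
            x = x0.copy()
            k1 = np.empty(n)
            k2 = np.empty(n)
            k3 = np.empty(n)
            k4 = np.empty(n)
            tmp = np.empty(n)
            h = t_end / n_steps
            states[0] = x
            row = 1
            for i in range(1, n_steps + 1):
                rhs_terms(coef, expo, target, x, k1)
                for j in range(n):
                    tmp[j] = x[j] + 0.5 * h * k1[j]
                rhs_terms(coef, expo, target, tmp, k2)
                for j in range(n):
                    tmp[j] = x[j] + 0.5 * h * k2[j]
                rhs_terms(coef, expo, target, tmp, k3)
                for j in range(n):
                    tmp[j] = x[j] + h * k3[j]
                rhs_terms(coef, expo, target, tmp, k4)
                for j in range(n):
                    x[j] = x[j] + (h / 6.0) * (
                        k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]
                    )
                if i % save_every == 0 or i == n_steps:
                    states[row] = x
                    row += 1
            return row

        _KERNEL = run
    return _KERNEL


def rk4_mass_action(coef, expo, target, x0, t_end: float, n_steps: int,
                    n_save: int = 101):
    """Fixed-step RK4 over raw mass-action term arrays (numba fast path).

    ``coef``/``expo``/``target`` are the arrays produced by
    ``compile_rhs(scheme).term_arrays`` (or built independently): one row per
    signed term. Returns ``(times, states)`` like :func:`rk4`.
    """
    coef = np.ascontiguousarray(coef, dtype=np.float64)
    expo = np.ascontiguousarray(expo, dtype=np.float64)
    target = np.ascontiguousarray(target, dtype=np.int64)
    x0 = np.ascontiguousarray(x0, dtype=np.float64)
    save_every = max(1, n_steps // (n_save - 1))
    n_rows = 1 + n_steps // save_every + (1 if n_steps % save_every else 0)
    states = np.empty((n_rows, x0.size))
    rows = _kernel()(coef, expo, target, x0, float(t_end), n_steps,
                     save_every, states)
    h = t_end / n_steps
    saved_idx = [0] + [
        i for i in range(1, n_steps + 1)
        if i % save_every == 0 or i == n_steps
    ]
    times = np.asarray(saved_idx, dtype=float) * h
    return times, states[:rows][: len(times)]
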
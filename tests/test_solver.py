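"""Native implicit integrator: single steps, step control, accuracy, errors."""

import math

import numpy as np
import pytest

from netkin import (
    SimulationOptions,
    Trajectory,
    compile_rhs,
    integrate,
    models,
    step_backward_euler,
    step_gear2,
    step_trapezoidal,
)
from netkin.analysis import conservation_laws
from netkin.errors import (
    BlowupError,
    InvalidParameterError,
    StiffnessError,
)
from netkin.oracle import rk4, rk4_mass_action


def linear_rhs(lam):
    f = lambda t, x: -lam * x
    f.jacobian = lambda t, x: np.array([[-lam]])
    return f


class TestOptions:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SimulationOptions(total_time=-1.0).resolved()
        with pytest.raises(InvalidParameterError):
            SimulationOptions(total_time=1.0, print_step=2.0).resolved()
        with pytest.raises(InvalidParameterError):
            SimulationOptions(total_time=1.0, reltol=0.5).resolved()
        with pytest.raises(InvalidParameterError):
            SimulationOptions(total_time=1.0, method="rk45").resolved()
        with pytest.raises(InvalidParameterError):
            SimulationOptions(
                total_time=1.0, min_step=0.1, initial_step=0.01
            ).resolved()

    def test_defaults_derived_from_total_time(self):
        opts = SimulationOptions(total_time=10.0).resolved()
        assert opts.print_step == pytest.approx(0.05)
        assert opts.max_step == pytest.approx(1.0)
        assert opts.initial_step <= opts.max_step


class TestSingleSteps:
    @pytest.mark.parametrize("lam_h", [0.01, 0.1, 1.0, 3.0])
    def test_trapezoidal_is_the_pade_update_on_linear_problems(self, lam_h):
        f = linear_rhs(1.0)
        x1, _, _ = step_trapezoidal(f, np.array([1.0]), 0.0, lam_h,
                                    newton_tol=1e-6)
        expected = (1 - lam_h / 2) / (1 + lam_h / 2)
        assert x1[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("lam_h", [0.01, 0.5, 2.0])
    def test_gear2_constant_step_formula_on_linear_problems(self, lam_h):
        """x1 = (4 x0 - x_prev)/3 + (2h/3) f(x1), solved in closed form."""
        f = linear_rhs(1.0)
        x_prev = np.array([math.exp(lam_h)])  # history point at t = -h
        x0 = np.array([1.0])
        x1, _, _ = step_gear2(f, x_prev, x0, 0.0, lam_h, newton_tol=1e-6)
        expected = (4 * x0[0] - x_prev[0]) / 3 / (1 + 2 * lam_h / 3)
        assert x1[0] == pytest.approx(expected, rel=1e-12)

    def test_both_methods_a_stable_on_decay(self):
        """A-stability on x' = -lambda x for any lambda h > 0: trapezoidal
        damps every step; both roots of the BDF2 two-step recursion stay in
        the unit disc."""
        f = linear_rhs(1.0)
        for lam_h in np.logspace(-2, 3, 21):
            x_tr, _, _ = step_trapezoidal(f, np.array([1.0]), 0.0, lam_h)
            assert abs(x_tr[0]) <= 1.0 + 1e-12
            # (1 + 2z/3) xi^2 - (4/3) xi + 1/3 = 0, z = lambda h
            roots = np.roots([1.0 + 2.0 * lam_h / 3.0, -4.0 / 3.0, 1.0 / 3.0])
            assert np.max(np.abs(roots)) <= 1.0 + 1e-12

    @pytest.mark.parametrize(
        "stepper, n_points",
        [(step_trapezoidal, None), (step_gear2, None)],
    )
    def test_second_order_convergence_on_logistic_growth(self, stepper, n_points):
        """Fixed-step error vs h has slope 2 +- 0.2 on a smooth nonlinear
        problem (logistic x' = x (1 - x))."""
        f = lambda t, x: x * (1.0 - x)
        f.jacobian = lambda t, x: np.array([[1.0 - 2 * x[0]]])

        def exact(t):
            return 0.1 * math.exp(t) / (1 - 0.1 + 0.1 * math.exp(t))

        t_end = 4.0
        errors = []
        hs = [0.2, 0.1, 0.05, 0.025, 0.0125]
        for h in hs:
            n = int(round(t_end / h))
            x = np.array([exact(0.0)])
            x_prev = np.array([exact(-h)])  # exact history seeds BDF2
            t = 0.0
            for _ in range(n):
                if stepper is step_gear2:
                    y, _, _ = step_gear2(f, x_prev, x, t, h, newton_tol=1e-6)
                else:
                    y, _, _ = stepper(f, x, t, h, newton_tol=1e-6)
                x_prev, x, t = x, y, t + h
            errors.append(abs(x[0] - exact(t_end)))
        slope = np.polyfit(np.log(hs), np.log(errors), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        fx = models.decay()
        rhs = compile_rhs(fx.scheme)
        for reltol in (1e-3, 1e-6):
            tr = integrate(
                rhs, fx.scheme.initial_state(),
                SimulationOptions(total_time=1.0, print_step=0.1, reltol=reltol),
            )
            assert tr.final_state[0] == pytest.approx(
                math.exp(-1.0), abs=10 * reltol
            )

    def test_rlc_series_circuit_matches_damped_oscillator_closed_form(self):
        """Series RLC with L=1, R=0.5, C=4 == mechanical m=1, b=0.5, k=0.25;
        both match the underdamped closed form to 1e-4 relative."""
        fx_el = models.oscillator(l=1.0, r=0.5, c=4.0)
        fx_me = models.oscillator(m=1.0, b=0.5, k=0.25)
        assert fx_el.scheme == fx_me.scheme
        rhs = compile_rhs(fx_el.scheme)
        opts = SimulationOptions(
            total_time=fx_el.options.total_time,
            print_step=fx_el.options.print_step,
            reltol=1e-6,
        )
        tr = integrate(rhs, fx_el.scheme.initial_state(), opts)
        g, w = 0.25, math.sqrt(0.25 - 0.0625)
        exact = np.exp(-g * tr.times) * (
            np.cos(w * tr.times) + (g / w) * np.sin(w * tr.times)
        )
        err = np.max(np.abs(tr.column("x") - exact)) / np.max(np.abs(exact))
        assert err < 1e-4

    def test_cycloaddition_conservation_and_equilibrium(
        self, diels_alder_fixture
    ):
        from conftest import scheme_equilibrium_conversion

        scheme = diels_alder_fixture.scheme
        rhs = compile_rhs(scheme)
        tr = integrate(
            rhs, scheme.initial_state(),
            SimulationOptions(total_time=1e14, print_step=1e12, reltol=1e-8),
        )
        # mass conservation along the whole trajectory
        assert np.max(np.abs(tr.column("A") + tr.column("C") - 1.0)) < 1e-6
        # A and B evolve identically
        assert np.max(np.abs(tr.column("A") - tr.column("B"))) < 1e-9
        k1 = scheme.constant("k1").value
        k2 = scheme.constant("k2").value
        c_eq = scheme_equilibrium_conversion(k1, k2)
        assert abs(tr.final_state[2] - c_eq) < 1e-6

    def test_print_grid_contract(self):
        fx = models.decay()
        tr = integrate(
            compile_rhs(fx.scheme), fx.scheme.initial_state(),
            SimulationOptions(total_time=1.0, print_step=0.1),
        )
        assert tr.times[0] == 0.0
        assert tr.times[-1] == pytest.approx(1.0)
        assert len(tr) == 11
        assert np.all(np.diff(tr.times) > 0)
        assert np.allclose(tr.states[0], fx.scheme.initial_state())

    def test_tolerance_refinement_monotonically_reduces_error(self):
        """Halving reltol through 1e-2 -> 1e-3 -> 1e-4 shrinks the max error
        against a tight-tolerance reference on the fixture set."""
        fixtures = [
            models.oscillator(m=1.0, b=0.5, k=0.25),
            models.decay_chain(k1=1.0, k2=10.0),
            models.reversible_pair(),
        ]
        max_errors = []
        for reltol in (1e-2, 1e-3, 1e-4):
            worst = 0.0
            for fx in fixtures:
                rhs = compile_rhs(fx.scheme)
                base = SimulationOptions(
                    total_time=fx.options.total_time,
                    print_step=fx.options.print_step,
                )
                ref = integrate(rhs, fx.scheme.initial_state(),
                                SimulationOptions(
                                    total_time=base.total_time,
                                    print_step=base.print_step,
                                    reltol=1e-9))
                tr = integrate(rhs, fx.scheme.initial_state(),
                               SimulationOptions(
                                   total_time=base.total_time,
                                   print_step=base.print_step,
                                   reltol=reltol))
                scale = np.max(np.abs(ref.states))
                worst = max(worst, float(
                    np.max(np.abs(tr.states - ref.states)) / scale))
            max_errors.append(worst)
        assert max_errors[0] > max_errors[1] > max_errors[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rk4_on_random_schemes(self, seed):
        scheme = models.random_scheme(4, 4, rng_seed=seed)
        rhs = compile_rhs(scheme)
        t_end = 5.0
        times, oracle_states = rk4_mass_action(
            *rhs.term_arrays, scheme.initial_state(), t_end, 10 ** 6,
            n_save=101,
        )
        tr = integrate(
            rhs, scheme.initial_state(),
            SimulationOptions(total_time=t_end, print_step=t_end / 100,
                              reltol=1e-6),
        )
        assert np.allclose(tr.times, times)
        scale = float(np.max(np.abs(oracle_states)))
        assert np.max(np.abs(tr.states - oracle_states)) / scale < 1e-4

    def test_stiff_scheme_needs_few_implicit_but_many_rk4_steps(self):
        """Rate constants six orders of magnitude apart: the implicit engine
        finishes in well under 1e4 accepted steps while explicit RK4 at its
        stability-limited step would need more than 1e6."""
        scheme = models.random_scheme(
            5, 5, rate_scale_range=(1.0, 1e6), rng_seed=7
        )
        rhs = compile_rhs(scheme)
        total_time = 10.0
        tr = integrate(rhs, scheme.initial_state(),
                       SimulationOptions(total_time=total_time, print_step=0.1))
        assert tr.meta["accepted"] < 10_000
        lam_max = float(np.max(np.abs(np.linalg.eigvals(
            rhs.jacobian(0.0, scheme.initial_state())))))
        rk4_stability_limit = 2.785 / lam_max
        assert total_time / rk4_stability_limit > 1e6

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_linear_conservation_laws_hold_along_trajectories(self, seed):
        scheme = models.random_scheme(5, 5, rng_seed=seed)
        rhs = compile_rhs(scheme)
        reltol = 1e-6
        tr = integrate(rhs, scheme.initial_state(),
                       SimulationOptions(total_time=5.0, print_step=0.05,
                                         reltol=reltol))
        laws = conservation_laws(scheme)
        assert laws.shape[1] >= 1
        invariants = tr.states @ laws
        drift = np.max(np.abs(invariants - invariants[0]))
        assert drift < 10 * reltol

    def test_blowup_reported_with_time(self):
        f = lambda t, x: x ** 2  # finite-time singularity at t = 1
        with pytest.raises((BlowupError, StiffnessError)):
            integrate(f, np.array([1.0]),
                      SimulationOptions(total_time=2.0, print_step=0.01))

    def test_nan_rhs_raises_blowup(self):
        f = lambda t, x: np.array([float("nan")])
        with pytest.raises(BlowupError):
            integrate(f, np.array([1.0]),
                      SimulationOptions(total_time=1.0, print_step=0.1))

    def test_csv_round_trip_to_formatting_precision(self):
        fx = models.decay()
        tr = integrate(compile_rhs(fx.scheme), fx.scheme.initial_state(),
                       SimulationOptions(total_time=1.0, print_step=0.1))
        lines = tr.to_csv(numdgt=9).strip().splitlines()
        assert lines[0] == "t,A,B"
        parsed = np.array([[float(v) for v in line.split(",")]
                           for line in lines[1:]])
        assert np.allclose(parsed[:, 0], tr.times, rtol=1e-8)
        assert np.allclose(parsed[:, 1:], tr.states, rtol=1e-8, atol=1e-12)

    def test_no_negativity_clamping(self):
        """Undershoot below zero is reported, not corrected: the oscillator
        coordinate must go negative."""
        fx = models.oscillator(m=1.0, b=0.1, k=1.0)
        tr = integrate(compile_rhs(fx.scheme), fx.scheme.initial_state(),
                       SimulationOptions(total_time=10.0, print_step=0.1))
        assert np.min(tr.column("x")) < -0.5
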
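# Methods

## The network analogy

netkin treats a system of first-order kinetic ODEs as an electrical
network. Every species is a circuit node whose voltage equals its
concentration (1 mol/l ↔ 1 V); the mapping has three elements per
equation:

* **Capacitor**, 1 F, node to ground. Its current is C·dV/dt, i.e. the
  time derivative of the concentration. Unit capacitance makes branch
  currents numerically equal to reaction rates, so no scale factors appear
  anywhere.
* **Voltage-controlled current sources**, one per mass-action addend
  s·m·k·∏[x]^α of the rate equation. A per-addend source (rather than one
  source carrying the whole right-hand side, which the analogy equally
  permits) keeps the exported netlist self-documenting and lets the
  Kirchhoff-law fidelity test compare term multisets instead of simplified
  expressions.
* **Continuity resistor**, node to ground, default 1 × 10¹⁵ Ω. It exists
  only so that every node has a DC path; it must not perturb the
  chemistry. With C = 1 F a resistance R adds a parasitic decay rate
  1/(RC): over the 10⁷ s cycloaddition horizon, 10¹² Ω would already
  contribute a ~10⁻⁵ relative drift, while 10¹⁵ Ω keeps the perturbation
  near 10⁻⁸ — comfortably below the 10⁻⁶ inertness bound the test suite
  enforces. The value is an argument of `build_network` for users who
  want the classic 10¹²Ω.

Kirchhoff's current law at each node — capacitor current equals the sum of
source currents minus the resistor leak — reproduces the species' rate
equation exactly; `NetworkModel.symbolic_rhs()` exposes the KCL balance
symbolically and the test suite proves term-for-term equality with the
scheme for every built-in model and for random schemes.

The netlist dialect is PSpice-flavoured: `C<name> <node> 0 1 IC=<x0>`
capacitor cards, behavioural `G<name> 0 <node> VALUE = { ... }` sources
(the `0 <node>` order injects positive current *into* the node, so the
printed expression is the signed rate term itself), `R` cards, and
`.OPTIONS RELTOL/NUMDGT`, `.TRAN <print> <total> UIC`, `.PRINT TRAN`
analysis cards. Powers are written `PWR(V(N_X),a)`. Element order is
species order then term order, so exports are byte-identical across runs.
`parse_cir` inverts exactly this dialect (a `* species:` comment preserves
original capitalisation); any other element card is rejected with its line
number. The package never shells out to a SPICE engine — the netlist is an
interchange artefact, the native solver does the integration.

## Rate constants

Directly specified, or computed from a transition-state free-energy
barrier by the Eyring equation k = (k_B·T/h)·exp(−ΔG‡/(R·T)) with
transmission coefficient 1. Physical constants are CODATA 2018 exact
values (k_B = 1.380649 × 10⁻²³ J/K, h = 6.62607015 × 10⁻³⁴ J·s,
R = 8.31446262 J mol⁻¹ K⁻¹ to nine significant digits), so barrier-derived
constants are bit-reproducible; a `RateConstant` of barrier origin
re-validates its stored value against the formula to 10⁻¹² relative.
Temperature is a required field wherever a barrier appears (file format:
`barrier:<J/mol>@<K>`); only the Diels-Alder fixture applies the package
default of 298.15 K, the conventional standard temperature, since no
temperature accompanies the published barrier pair. For multimolecular
terms the Eyring output (s⁻¹) is used as-is with mol/l concentrations,
i.e. the standard-state concentration c° = 1 mol/l is implied.

Negative barriers are accepted (exponential > 1) but logged, since they
usually indicate a sign mistake in user input.

## The transient engine

The integrator is the classic SPICE pair: **trapezoidal rule** and
**variable-coefficient BDF2** ("Gear-2"), both A-stable and second order,
under one adaptive driver.

* Startup: a single backward-Euler step (BDF1) seeds the two-point history
  BDF2 needs; the initial step is print_step × 10⁻⁶ unless set.
* Default policy (`tr-gear`): trapezoidal steps; when the per-component
  truncation-error estimate alternates in sign on consecutive accepted
  steps — trapezoidal ringing on stiff components — the driver switches to
  BDF2 for the next 20 steps. Pure `trapezoidal` and `gear2` modes exist
  for testing.
* Newton iteration solves each implicit step on the analytic Jacobian of
  the mass-action polynomial (exact partial derivatives, assembled
  term-wise); plain callables fall back to central differences.
  Convergence is a weighted update-norm test with a machine-precision
  floor; non-convergence rejects the step and halves h (quarter after two
  consecutive failures) rather than aborting.
* Error estimates: trapezoidal uses the second divided difference of f
  through a cubic-Hermite midpoint evaluation, h(f₀ − 2f_m + f₁)/3 ≈
  h³x‴/12, one extra function evaluation per step and no history coupling;
  BDF2 uses 0.4 × (corrector − quadratic predictor), the constant-step
  ratio of its −(2/9)h³x‴ truncation error to the predictor-corrector
  gap; backward Euler uses its h²x″/2 leading term.
* Step control: accept when the estimate is below 0.1 × (reltol·|x| +
  abstol) componentwise; the 0.1 margin absorbs the accumulation of
  per-step errors into the global error, keeping realised global errors of
  smooth problems within a few reltol (measured: without it, tight
  tolerances landed at 14–65 × reltol). New step = h × clip(0.9 ×
  (tol/err)^(1/3), 0.2, 5); two consecutive rejections at least halve h.
  abstol defaults to 10⁻¹² mol/l — an absolute floor is mandatory when
  concentrations pass through zero.
* Output: accepted steps live on an irregular mesh; the print grid is
  filled by cubic Hermite interpolation using the stored derivatives, so
  printing never constrains the mesh. `RELTOL` defaults to 10⁻³ (the
  SPICE convention); `NUMDGT` controls only significant digits in text
  output, never arithmetic.
* Concentrations are not clamped at zero: tolerance-level undershoot is
  reported as computed. Clamping would silently mask controller bugs and
  break the linear conservation laws the tests check.

Failure modes are first-class: step-size underflow and persistent Newton
failure raise a stiffness error carrying the failing time; NaN/Inf in the
state or right-hand side raises a blow-up error.

### Validation

The dual-route checks are: (1) a hand-written fixed-step classical RK4
(numba-compiled over the raw term arrays, an independent re-implementation
of the mass-action evaluation) run at 10⁶ steps against the native solver
on 20 seeded random schemes; (2) closed forms for decay, chain,
reversible pair and the damped oscillator; (3) Richardson slope ≈ 2 on a
smooth nonlinear problem; (4) left-null-space conservation laws constant
along trajectories; (5) a six-decade stiff scheme that completes in a few
hundred implicit steps where the explicit stability limit implies > 10⁶.

## Random schemes

`random_scheme` draws reactions from count-conserving templates (A→B,
A+B→C+D, 2A→B+C, optionally reversible), so the all-ones vector is always
conserved, mass-action dynamics keep states non-negative and trajectories
bounded — the regime in which a fixed-step oracle comparison is meaningful.
Rate constants are log-uniform over `rate_scale_range` with the two range
endpoints always present once two reactions exist, making the stiffness
ratio a constructive guarantee. Initial concentrations are uniform on
[0.2, 1]. An `closed=False` variant adds a count-breaking template for
structural tests. What these schemes do *not* emulate: zeroth-order feeds,
third-order termolecular steps, or near-singular Jacobians; passing the
oracle suite therefore demonstrates correctness of the integrator on
well-posed bounded mass-action systems, not robustness to arbitrary ODEs.

## Steady states and the SSA

Plateau detection works on the print grid: the trajectory has reached a
steady state at the earliest print point after which every species'
change per print step stays below the threshold (default 10⁻⁶) *relative
to that species' amplitude over the run*. The amplitude-relative
denominator is deliberate: a species decaying exponentially to zero has a
constant |Δx|/|x| per step and would never plateau under a
pointwise-relative rule, yet is stationary by any physical reading.

`ssa_solve` clamps the non-intermediates and solves the intermediate
equations by damped Newton (backtracking halving, analytic sub-Jacobian),
with ten log-spaced positive restarts. Convergence requires the residual
below 10⁻¹⁰ *and* below 10⁻⁸ times the largest individual addend at the
root: the relative condition is what keeps systems whose natural rate
scale is far below 10⁻¹⁰ (e.g. atmospheric mechanisms in mol/l·s) from
"converging" at a point that is nowhere near a root. Symbolic elimination
is used only as a test-side oracle, so arbitrary mechanisms work.

`compare_ssa` integrates the full scheme over the caller's horizon, takes
the plateau values, solves the SSA with non-intermediates clamped at their
initial concentrations, and reports the per-intermediate ratio full/SSA,
flagging species whose ratio deviates from 1 by more than a factor
(default 2). The comparison is meaningful on horizons over which the
clamped species genuinely stay near their initial values — which is
exactly the regime where the approximation claims validity, and is how the
validity-vs-separation tests are set up (horizon ∝ 1/k_fast).

## Chaos diagnostics

`lyapunov_max` implements the Benettin two-trajectory method: a companion
displaced by 10⁻⁸·‖x₀‖ evolves alongside the reference; every
renormalisation interval (default 1 time unit) the log stretch of the
separation is recorded and the companion is pulled back to the reference
distance. The exponent is the mean stretch rate over the second half of
the horizon (first half discarded as transient) with the standard error
of that mean. Segments are propagated either by the native adaptive
solver (default; right choice for short horizons and linear benchmarks,
where the estimate matches dominant eigenvalues within a few percent) or
by fixed-step RK4 over the compiled term arrays (`integrator="rk4"`), the
economical choice for the 10³-unit horizons chaotic attractors need.

The peroxidase-oxidase demonstrations use k₁ = 0.35, k₂ = 250,
k₃ = 0.035, k₄ = 20, k₅ = 5.35, k₆ = 10⁻⁵, k₇ = 0.1, k₈ = 0.825 with
oxygen feed level 8 and initial state (4, 80, 0.01, 0.01), dimensionless.
This is the package's own demonstration choice, located by scanning k₁
across the model's oscillatory window for a robustly positive largest
Lyapunov exponent (λ ≈ 0.03 per time unit, stable under halving or
doubling of the renormalisation interval and under horizon changes); the
model structure makes k₁…k₈ required user arguments precisely so that no
invented numbers masquerade as a published parameter set.

## Scheme file and CSV conventions

The scheme format is versioned (`# netkin scheme v1`), line-oriented,
UTF-8 with `#` comments: `[species]` name = initial concentration,
`[constants]` name = value or `barrier:<ΔG>@<T>`, `[equations]` one
`d[X]/dt = ...` per species with terms `[mult*]const[*species[^exp]]` and
`0` for an empty right-hand side. Floats are written with `repr`, so
read(write(s)) is field-for-field exact, including barrier-derived
constants. Species/constant names share one namespace per scheme
(`[A-Za-z][A-Za-z0-9_]*`), which is what makes the equation grammar
unambiguous without quoting.

CSV outputs (trajectories, SSA reports, phase-space clouds) format values
to NUMDGT significant digits; the CLI logs a machine-parseable
`key=value` summary to stderr and keeps stdout/file for data.

## Known limitations

* Rate laws must be polynomial (mass-action); Michaelis-Menten forms must
  be pre-expanded by the user. Non-integer exponents are accepted but
  undefined for negative concentrations.
* BDF2 is the highest Gear order; no DAE support, no event detection.
* The steady-state detector works on the print grid: a plateau shorter
  than one print step is invisible.
* Only the largest Lyapunov exponent is estimated, not the spectrum; no
  bifurcation continuation or Poincaré sections.
* The netlist dialect targets ngspice/PSpice ABM compatibility; it is an
  export/import format, not a claim of byte compatibility with any other
  tool's CIR output.
* Temperature is fixed per run; there is no temperature ramping.
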